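"""Synthetic cohort generator.

Produces OTU count tables plus clinical metadata with the statistical
structure the downstream analysis assumes: subjects contributing repeated
samples, sparse long-tailed compositional counts with subject-level
correlation, and a planted panel of discriminatory OTUs whose relative
abundance shifts in active-disease samples.

Generative model (fixed, seedable):

1. A global OTU relative-abundance profile is drawn from a log-normal and
   normalised (long-tailed ranks).
2. Each subject gets a sparsity mask (non-discriminatory OTUs dropped
   independently with probability ``sparsity``) and a baseline composition
   drawn from a Dirichlet centred on the masked global profile with total
   concentration ``subject_dispersion``.
3. Sample states are assigned so that ``active_fraction`` of all samples is
   active.  In active samples, half of the discriminatory OTUs are
   up-weighted by ``effect_size`` and half down-weighted by ``1/effect_size``
   on the relative-abundance scale, then renormalised.
4. Counts are multinomial at a per-sample depth drawn from
   Normal(depth_mean, depth_sd), truncated below at ``min_depth`` (default 1;
   set it to the rarefaction depth to guarantee no synthetic sample is
   dropped).
5. Clinical values (HBI, CRP, FC) are drawn consistently with the planted
   state so activity labelling recovers it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seeding import stage_rng
from .tables import OtuTable

_PHYLA = (
    "Bacteroidetes",
    "Firmicutes",
    "Proteobacteria",
    "Actinobacteria",
    "Fusobacteria",
    "Verrucomicrobia",
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort."""

    n_subjects: int = 71
    samples_per_subject_range: tuple[int, int] = (1, 8)
    n_otus: int = 2000
    n_discriminatory: int = 50
    effect_size: float = 4.0
    subject_dispersion: float = 50.0
    depth_mean: float = 8333.0
    depth_sd: float = 1500.0
    sparsity: float = 0.3
    active_fraction: float = 0.5
    seed: int = 0
    min_depth: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.samples_per_subject_range
        if self.n_subjects <= 0 or self.n_otus <= 0 or lo <= 0 or hi < lo:
            raise ValueError("counts must be positive and range ordered")
        if not (0 <= self.n_discriminatory <= self.n_otus):
            raise ValueError("n_discriminatory must be in [0, n_otus]")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.subject_dispersion <= 0:
            raise ValueError("subject_dispersion must be positive")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must be in [0, 1)")
        if not (0 <= self.active_fraction <= 1):
            raise ValueError(
                "active_fraction must be in [0, 1]; a larger value would "
                "require more active samples than exist"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def clinicals_from_state(
    state: str, rng: np.random.Generator
) -> tuple[int, float, float]:
    """Draw (HBI, CRP, FC) consistent with the planted disease state.

    Active samples get FC uniform in (259, 4900) — always > 250, the
    activity criterion; HBI and CRP are unconstrained draws.  Remission
    samples get HBI in 0-4, CRP in (0, 4.7), FC in (14, 98), jointly
    satisfying the remission rule.
    """
    if state == "active":
        hbi = int(rng.integers(0, 17))
        crp = float(rng.uniform(0.0, 60.0))
        fc = float(rng.uniform(259.0, 4900.0))
    elif state == "remission":
        hbi = int(rng.integers(0, 5))
        crp = float(rng.uniform(0.0, 4.7))
        fc = float(rng.uniform(14.0, 98.0))
    else:
        raise ValueError(f"unknown state {state!r}")
    return hbi, crp, fc


def generate_cohort(
    spec: CohortSpec,
) -> tuple[OtuTable, pd.DataFrame, set[str]]:
    """Generate (OtuTable, metadata frame, set of discriminatory OTU ids).

    Deterministic: the same spec (including seed) yields bit-identical
    output.
    """
    rng = stage_rng(spec.seed, "simulate")
    n_otus = spec.n_otus

    otu_ids = [f"OTU{j:05d}" for j in range(n_otus)]
    phyla = rng.choice(len(_PHYLA), size=n_otus, p=_phylum_weights())
    taxonomy = [
        f"k__Bacteria;p__{_PHYLA[p]};c__;o__;f__;g__;s__" for p in phyla
    ]

    # global long-tailed profile
    global_profile = rng.lognormal(mean=0.0, sigma=2.0, size=n_otus)
    global_profile /= global_profile.sum()

    # plant discriminatory OTUs among the more abundant quartile so they are
    # detectable after rarefaction and would survive a prevalence filter
    candidates = np.argsort(global_profile)[::-1][: max(n_otus // 4, spec.n_discriminatory)]
    disc = rng.choice(candidates, size=spec.n_discriminatory, replace=False)
    half = spec.n_discriminatory // 2
    disc_up = disc[:half] if spec.n_discriminatory > 1 else disc
    disc_down = disc[half:] if spec.n_discriminatory > 1 else np.array([], int)
    truth = {otu_ids[j] for j in disc}

    lo, hi = spec.samples_per_subject_range
    subject_ids = [f"S{k:03d}" for k in range(spec.n_subjects)]
    samples_per_subject = rng.integers(lo, hi + 1, size=spec.n_subjects)
    n_samples = int(samples_per_subject.sum())

    n_active = int(round(spec.active_fraction * n_samples))
    states = np.array(["remission"] * n_samples, dtype=object)
    states[rng.permutation(n_samples)[:n_active]] = "active"

    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    locations = rng.choice(["L1", "L2", "L3"], size=spec.n_subjects)
    colectomy = rng.integers(0, 2, size=spec.n_subjects)
    ages = rng.integers(18, 71, size=spec.n_subjects)

    row = 0
    for k, subj in enumerate(subject_ids):
        # subject sparsity mask; planted OTUs always retained so the signal
        # is never masked away
        mask = rng.random(n_otus) >= spec.sparsity
        mask[disc] = True
        base = global_profile * mask
        base /= base.sum()
        alpha = np.where(mask, spec.subject_dispersion * base, 0.0)
        baseline = np.zeros(n_otus)
        baseline[mask] = rng.dirichlet(alpha[mask])
        for s in range(int(samples_per_subject[k])):
            sid = f"{subj}.V{s + 1}"
            sample_ids.append(sid)
            state = str(states[row])
            comp = baseline.copy()
            if state == "active" and spec.effect_size > 1:
                comp[disc_up] *= spec.effect_size
                comp[disc_down] /= spec.effect_size
                comp /= comp.sum()
            depth = int(round(rng.normal(spec.depth_mean, spec.depth_sd)))
            depth = max(depth, spec.min_depth)
            counts[row] = rng.multinomial(depth, comp)
            hbi, crp, fc = clinicals_from_state(state, rng)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subj,
                    "hbi": hbi,
                    "crp": round(crp, 2),
                    "fc": round(fc, 1),
                    "days_since_antibiotics": int(rng.integers(60, 400)),
                    "mesalazine": int(rng.integers(0, 2)),
                    "thiopurine": int(rng.integers(0, 2)),
                    "biological": int(rng.integers(0, 2)),
                    "disease_location": locations[k],
                    "colectomy": int(colectomy[k]),
                    "age": int(ages[k]),
                }
            )
            row += 1

    table = OtuTable(
        counts=counts, sample_ids=sample_ids, otu_ids=otu_ids, taxonomy=taxonomy
    )
    meta = pd.DataFrame(meta_rows)
    return table, meta, truth


def _phylum_weights() -> np.ndarray:
    # dominant Bacteroidetes/Firmicutes, rare Fusobacteria/Verrucomicrobia
    w = np.array([0.40, 0.40, 0.10, 0.06, 0.02, 0.02])
    return w / w.sum()
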