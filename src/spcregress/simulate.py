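"""Seeded generators of synthetic spectral-count datasets and PSM tables.

The count generator emulates the structure of a two-series biomarker
study: two outcome groups (regression / persistence of a CIN2-3 lesion)
of 20 patients each, each split into a learning and a validation half of
10; a background of proteins whose detection probability is shared by the
groups; and a small set of *planted* discriminator proteins whose
per-group presence probabilities mirror the presence patterns of the
ZNF441/PLD6 markers (present in ~95% / 60% of regression samples,
absent in persistence).  Counts, when a protein is present, are
negative-binomial (overdispersed Poisson) with a per-sample log-normal
depth factor.

The PSM generator emits a *boundary battery*: peptide-spectrum matches
engineered to sit exactly at and just beside every acceptance-rule
boundary (Xcorr at/below the charge threshold, peptide length 6/7, ion
runs of 2/3, per-sample occurrence 2/3), together with a machine-readable
expectation — computed by an independent rule evaluator at generation
time — of which proteins identification filtering must accept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .filtering import FilterPolicy
from .io import PSMRecord
from .matrix import SpectralCountMatrix


@dataclass(frozen=True)
class PlantedProtein:
    """A discriminator protein with group-specific presence probabilities."""

    accession: str
    presence_prob_regression: float
    presence_prob_persistence: float
    mean_count_when_present: float = 3.0

    def __post_init__(self) -> None:
        for p in (self.presence_prob_regression, self.presence_prob_persistence):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"presence probability outside [0,1]: {p}")
        if self.mean_count_when_present <= 0:
            raise ValueError("mean_count_when_present must be > 0")


def default_planted() -> Tuple[PlantedProtein, ...]:
    """The two default discriminators, mirroring the ZNF441/PLD6 patterns."""
    return (
        PlantedProtein("ZNF441_like", 0.95, 0.0, 3.0),
        PlantedProtein("PLD6_like", 0.60, 0.0, 3.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic count generator.

    Defaults reproduce the emulated study: 20 + 20 samples split 10/10
    into learning and validation halves, 163 background proteins plus the
    two planted discriminators (165 total), moderately overdispersed
    counts and mild per-sample depth variation.
    """

    n_regression: int = 20
    n_persistence: int = 20
    n_background_proteins: int = 163
    planted: Tuple[PlantedProtein, ...] = field(default_factory=default_planted)
    background_presence_prob: float = 0.7
    background_mean_count: float = 5.0
    count_dispersion: float = 2.0  # NB size parameter; large -> Poisson
    depth_sigma: float = 0.3  # sd of log-normal per-sample depth factor
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_presence_prob <= 1.0):
            raise ValueError("background_presence_prob outside [0,1]")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.depth_sigma < 0:
            raise ValueError("depth_sigma must be >= 0")
        if self.n_regression < 2 or self.n_persistence < 2:
            raise ValueError("need at least 2 samples per group")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draws with given means and shared size (dispersion)."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_spc_dataset(cfg: SimConfig) -> SpectralCountMatrix:
    """Generate a proteins x samples spectral-count matrix from the config.

    Per protein and sample, presence is Bernoulli with the group-specific
    (planted) or shared (background) probability; present entries draw a
    negative-binomial count with the configured mean scaled by the
    sample's depth factor, floored at 1 so that presence always leaves a
    detectable count.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)

    sample_ids: List[str] = []
    group_of: Dict[str, str] = {}
    split_of: Dict[str, str] = {}
    for group, n in (("regression", cfg.n_regression), ("persistence", cfg.n_persistence)):
        half = n // 2
        for i in range(n):
            sid = f"{group[:3]}_{i + 1:02d}"
            sample_ids.append(sid)
            group_of[sid] = group
            split_of[sid] = "learning" if i < half else "validation"

    n_samples = len(sample_ids)
    depth = (
        rng.lognormal(mean=0.0, sigma=cfg.depth_sigma, size=n_samples)
        if cfg.depth_sigma > 0
        else np.ones(n_samples)
    )
    is_regression = np.array([group_of[s] == "regression" for s in sample_ids])

    protein_ids = [p.accession for p in cfg.planted] + [
        f"BG_{i + 1:04d}" for i in range(cfg.n_background_proteins)
    ]
    counts = np.zeros((len(protein_ids), n_samples), dtype=int)

    for row, prot in enumerate(cfg.planted):
        prob = np.where(
            is_regression, prot.presence_prob_regression, prot.presence_prob_persistence
        )
        present = rng.random(n_samples) < prob
        mean = prot.mean_count_when_present * depth
        drawn = _nb_counts(rng, mean, cfg.count_dispersion)
        counts[row] = np.where(present, np.maximum(drawn, 1), 0)

    n_bg = cfg.n_background_proteins
    if n_bg:
        present = rng.random((n_bg, n_samples)) < cfg.background_presence_prob
        mean = np.broadcast_to(cfg.background_mean_count * depth, (n_bg, n_samples))
        drawn = _nb_counts(rng, mean, cfg.count_dispersion)
        counts[len(cfg.planted):] = np.where(present, np.maximum(drawn, 1), 0)

    return SpectralCountMatrix(
        counts=counts,
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        group_of=group_of,
        split_of=split_of,
    )


# ---------------------------------------------------------------------------
# PSM boundary battery


def _independent_accept(
    psms: Sequence[PSMRecord], policy: FilterPolicy
) -> Set[str]:
    """Reference evaluation of the acceptance rules, written to be obviously
    correct rather than fast, and kept free of any code shared with the
    filtering module."""

    def run_len(ions: Sequence[int]) -> int:
        s = sorted(ions)
        best = 0
        for start in range(len(s)):
            length = 1
            while start + length < len(s) and s[start + length] == s[start + length - 1] + 1:
                length += 1
            best = max(best, length)
        return best

    def xcorr_ok(p: PSMRecord) -> bool:
        if p.charge <= 2:
            thr = policy.xcorr_by_charge["2"]
        elif p.charge == 3:
            thr = policy.xcorr_by_charge["3"]
        else:
            thr = policy.xcorr_by_charge["4plus"]
        return p.xcorr >= thr

    def ions_ok(p: PSMRecord) -> bool:
        b, y = run_len(list(p.b_ions)), run_len(list(p.y_ions))
        k = policy.min_consecutive_ions
        if policy.consecutive_ion_mode == "both_series":
            return b >= k and y >= k
        return b >= k or y >= k

    passing = [p for p in psms if xcorr_ok(p)]
    accepted: Set[str] = set()
    for acc in {p.accession for p in passing}:
        recs = [p for p in passing if p.accession == acc]
        peptides = {p.peptide for p in recs}
        if len(peptides) >= 2:
            accepted.add(acc)
            continue
        pep = next(iter(peptides))
        if len(pep) < policy.min_peptide_length:
            continue
        if not any(ions_ok(p) for p in recs):
            continue
        occ_ok = False
        for sample in {p.sample_id for p in recs}:
            if sum(1 for p in recs if p.sample_id == sample) >= policy.min_occurrences_per_sample:
                occ_ok = True
        if occ_ok:
            accepted.add(acc)
    return accepted


@dataclass
class PSMBattery:
    """Engineered PSMs plus the independently computed acceptance expectation."""

    psms: List[PSMRecord]
    expected_accepted: Set[str]
    expected_rejected: Set[str]


def generate_psm_table(cfg: SimConfig, policy: FilterPolicy) -> PSMBattery:
    """Emit PSMs probing every acceptance-rule boundary.

    One protein per combination of (charge class, Xcorr at vs just below
    threshold, peptide length 6 vs 7, longest ion run 2 vs 3, per-sample
    occurrences 2 vs 3), plus multi-peptide proteins exercising the
    two-peptide acceptance path.  The expectation is evaluated by an
    independent brute-force rule checker at generation time, so the
    battery doubles as an oracle for the filtering module.
    """
    rng = np.random.default_rng(cfg.seed)
    psms: List[PSMRecord] = []
    sample = "bat_01"

    pep7 = "ACDEFGH"
    pep6 = "ACDEFG"
    charges = [(2, policy.xcorr_by_charge["2"]), (3, policy.xcorr_by_charge["3"]),
               (4, policy.xcorr_by_charge["4plus"]), (5, policy.xcorr_by_charge["4plus"])]
    k = policy.min_consecutive_ions
    ions_pass = frozenset(range(1, k + 1))  # run of exactly k
    ions_fail = frozenset(range(1, k)) if k > 1 else frozenset()
    combos = itertools.product(
        charges,
        (0.0, -0.01),  # xcorr delta from threshold
        (pep7, pep6),
        (ions_pass, ions_fail),
        (policy.min_occurrences_per_sample, policy.min_occurrences_per_sample - 1),
    )
    for idx, ((z, thr), delta, pep, ions, n_occ) in enumerate(combos):
        acc = f"SP_{idx:03d}"
        for _ in range(max(n_occ, 1)):
            psms.append(
                PSMRecord(
                    sample_id=sample,
                    accession=acc,
                    peptide=pep,
                    charge=z,
                    xcorr=max(thr + delta, 0.0),
                    b_ions=ions,
                    y_ions=frozenset(),
                )
            )

    # multi-peptide path: two unique passing peptides, one of them short
    psms.append(PSMRecord(sample, "MP_000", "ACDEFGHIK", 2,
                          policy.xcorr_by_charge["2"] + 0.5, frozenset({1, 2, 3})))
    psms.append(PSMRecord(sample, "MP_000", pep6, 2,
                          policy.xcorr_by_charge["2"] + 0.5, frozenset()))
    # multi-peptide but one peptide fails Xcorr -> effectively single-peptide
    psms.append(PSMRecord(sample, "MP_001", "ACDEFGHIK", 2,
                          max(policy.xcorr_by_charge["2"] - 0.01, 0.0), frozenset({1, 2, 3})))
    for _ in range(policy.min_occurrences_per_sample):
        psms.append(PSMRecord(sample, "MP_001", pep7, 2,
                              policy.xcorr_by_charge["2"], frozenset(), frozenset({2, 3, 4})))

    order = rng.permutation(len(psms))
    psms = [psms[i] for i in order]
    expected = _independent_accept(psms, policy)
    all_acc = {p.accession for p in psms}
    return PSMBattery(
        psms=psms,
        expected_accepted=expected,
        expected_rejected=all_acc - expected,
    )
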