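"""Spectral-count matrices and their normalization.

A spectral count (SPC) is the number of peptide-spectrum matches attributed
to a protein in one LC-MS/MS run; it is a label-free proxy for protein
abundance.  The study design carries a two-level outcome per sample
(``regression`` vs ``persistence`` of a CIN2-3 lesion) and a two-level
split (``learning`` vs ``validation`` patient series).

Normalization follows the published recipe: all counts are first offset by
+1 so that an undetected protein has count 1 (this also makes the
"<=1 versus >1" detection threshold meaningful downstream), then each entry
is rescaled by its sample's total count relative to the group-average
total.  Two readings of that rescaling are provided, see
:func:`normalize_spc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal

import numpy as np

GROUPS = ("regression", "persistence")
SPLITS = ("learning", "validation")

Group = Literal["regression", "persistence"]
Split = Literal["learning", "validation"]


class NormalizationError(ValueError):
    """Raised on invalid normalization requests (double offset, empty group...)."""


@dataclass
class SpectralCountMatrix:
    """Proteins x samples integer spectral counts with sample metadata.

    Attributes
    ----------
    counts
        ``(n_proteins, n_samples)`` nonnegative integer array.
    protein_ids, sample_ids
        Ordered accession / sample tokens matching the array axes.
    group_of
        Map sample id -> ``"regression"`` or ``"persistence"``.
    split_of
        Map sample id -> ``"learning"`` or ``"validation"``; may be empty
        when the split is irrelevant (e.g. a single-series matrix).
    offset_applied
        True once the +1 offset has been added (every entry >= 1).
    """

    counts: np.ndarray
    protein_ids: List[str]
    sample_ids: List[str]
    group_of: Dict[str, Group]
    split_of: Dict[str, Split] = field(default_factory=dict)
    offset_applied: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (proteins x samples)")
        n_prot, n_samp = self.counts.shape
        if n_prot != len(self.protein_ids) or n_samp != len(self.sample_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.protein_ids)} proteins / {len(self.sample_ids)} samples"
            )
        if len(set(self.protein_ids)) != n_prot:
            raise ValueError("duplicate protein ids")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("negative spectral counts")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        bad = {s: v for s, v in self.split_of.items() if v not in SPLITS}
        if bad:
            raise ValueError(f"unknown split labels: {bad}")
        if self.offset_applied and np.any(self.counts < 1):
            raise ValueError("offset_applied but entries < 1 present")

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_array(self) -> np.ndarray:
        """Group label per sample, aligned with the sample axis."""
        return np.array([self.group_of[s] for s in self.sample_ids])

    def y(self) -> np.ndarray:
        """Binary response coding: regression = 0, persistence = 1."""
        return (self.group_array() == "persistence").astype(float)

    def samples_in_group(self, group: Group) -> List[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def subset_samples(self, sample_ids: List[str]) -> "SpectralCountMatrix":
        """Column subset in the given order (labels carried along)."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SpectralCountMatrix(
            counts=self.counts[:, idx].copy(),
            protein_ids=list(self.protein_ids),
            sample_ids=list(sample_ids),
            group_of={s: self.group_of[s] for s in sample_ids},
            split_of={s: self.split_of[s] for s in sample_ids if s in self.split_of},
            offset_applied=self.offset_applied,
        )


@dataclass
class NormalizedMatrix:
    """Normalized spectral counts plus the audit quantities used to build them.

    ``sample_sums`` are per-sample totals of the offset counts and
    ``group_avg`` the within-group mean of those totals — the two symbols in
    the normalization formula.
    """

    values: np.ndarray
    mode: Literal["as_printed", "depth_corrected"]
    protein_ids: List[str]
    sample_ids: List[str]
    group_of: Dict[str, Group]
    split_of: Dict[str, Split]
    sample_sums: np.ndarray
    group_avg: Dict[str, float]

    def group_array(self) -> np.ndarray:
        return np.array([self.group_of[s] for s in self.sample_ids])

    def y(self) -> np.ndarray:
        return (self.group_array() == "persistence").astype(float)


def add_offset(m: SpectralCountMatrix) -> SpectralCountMatrix:
    """Add 1 to every count so no entry is zero.

    Raises
    ------
    NormalizationError
        If the offset has already been applied (applying it twice would
        silently corrupt the detection threshold semantics).
    """
    if m.offset_applied:
        raise NormalizationError("offset already applied to this matrix")
    return replace(m, counts=m.counts + 1, offset_applied=True)


def normalize_spc(
    m: SpectralCountMatrix,
    mode: Literal["as_printed", "depth_corrected"] = "as_printed",
) -> NormalizedMatrix:
    """Normalize offset spectral counts by sample totals and group averages.

    Two modes implement the two readings of the published formula:

    ``as_printed``
        ``value = SPC * sample_sum / group_avg`` — the formula exactly as
        printed.  Note this scales *deep* samples up.
    ``depth_corrected``
        ``value = SPC * group_avg / sample_sum`` — the conventional
        depth-normalizing inversion, under which doubling a sample's
        sequencing depth leaves its normalized values unchanged
        (up to the group-average recomputation).

    Group averages are computed over the samples present in *this* matrix,
    so learning and validation series normalized separately use their own
    averages.
    """
    if not m.offset_applied:
        raise NormalizationError("apply add_offset before normalizing")
    if mode not in ("as_printed", "depth_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    groups = m.group_array()
    sample_sums = m.counts.sum(axis=0).astype(float)
    group_avg: Dict[str, float] = {}
    for g in GROUPS:
        mask = groups == g
        if mask.any():
            group_avg[g] = float(sample_sums[mask].mean())
    present_groups = {m.group_of[s] for s in m.sample_ids}
    absent = [g for g in GROUPS if g not in present_groups]
    if absent and len(present_groups) == 0:
        raise NormalizationError("matrix has no labelled samples")

    avg_per_sample = np.array([group_avg[m.group_of[s]] for s in m.sample_ids])
    if mode == "as_printed":
        factor = sample_sums / avg_per_sample
    else:
        factor = avg_per_sample / sample_sums
    values = m.counts.astype(float) * factor[np.newaxis, :]
    return NormalizedMatrix(
        values=values,
        mode=mode,
        protein_ids=list(m.protein_ids),
        sample_ids=list(m.sample_ids),
        group_of=dict(m.group_of),
        split_of=dict(m.split_of),
        sample_sums=sample_sums,
        group_avg=group_avg,
    )
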