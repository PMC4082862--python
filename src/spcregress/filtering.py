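"""Multistep peptide/protein acceptance from peptide-spectrum matches.

The acceptance procedure mirrors the high-significance filtering used in
shotgun proteomics with a SEQUEST-style search engine:

1. an Xcorr gate whose threshold depends on precursor charge
   (1.9 at z=2, 2.3 at z=3, 2.6 at z>=4);
2. for proteins identified by a *single* unique peptide, extra credibility
   rules on that peptide: length >= 7 residues, at least three consecutive
   matched fragment ions, and >= 3 occurrences within one sample;
3. a group-presence rule: a protein is kept only if detected in at least
   30% of the samples of one outcome group.

Proteins with two or more unique peptides are accepted on the Xcorr gate
alone.  Spectral counts per protein and sample are the number of kept PSMs
mapping to the accession; no shared-peptide parsimony is attempted.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Mapping, Sequence, Set, Tuple

from .io import PSMRecord
from .matrix import SpectralCountMatrix


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the acceptance procedure; all comparisons are inclusive."""

    xcorr_by_charge: Mapping[str, float] = None  # keys "2", "3", "4plus"
    min_peptide_length: int = 7
    min_consecutive_ions: int = 3
    min_occurrences_per_sample: int = 3
    min_group_presence_fraction: float = 0.30
    consecutive_ion_mode: Literal["either_series", "both_series"] = "either_series"

    def __post_init__(self) -> None:
        if self.xcorr_by_charge is None:
            object.__setattr__(
                self, "xcorr_by_charge", {"2": 1.9, "3": 2.3, "4plus": 2.6}
            )
        if any(v < 0 for v in self.xcorr_by_charge.values()):
            raise ValueError("Xcorr thresholds must be nonnegative")
        if not (0 < self.min_group_presence_fraction <= 1):
            raise ValueError("min_group_presence_fraction must be in (0, 1]")
        if self.consecutive_ion_mode not in ("either_series", "both_series"):
            raise ValueError(f"bad consecutive_ion_mode {self.consecutive_ion_mode!r}")

    def xcorr_threshold(self, charge: int) -> float:
        # z=1 is gated like z=2: data-dependent acquisition selects z>=2,
        # so this path is defensive rather than calibrated.
        if charge <= 2:
            return self.xcorr_by_charge["2"]
        if charge == 3:
            return self.xcorr_by_charge["3"]
        return self.xcorr_by_charge["4plus"]


@dataclass
class AcceptedProtein:
    """A protein surviving identification filtering, with per-sample counts."""

    accession: str
    unique_peptides: Set[str]
    spc_by_sample: Dict[str, int]
    single_peptide_flag: bool
    blast_confirmation_pending: bool = False

    def __post_init__(self) -> None:
        if not self.unique_peptides:
            raise ValueError("accepted protein must have at least one peptide")
        if any(c < 0 for c in self.spc_by_sample.values()):
            raise ValueError("negative spectral counts")
        if self.single_peptide_flag != (len(self.unique_peptides) == 1):
            raise ValueError("single_peptide_flag inconsistent with peptide set")


def passes_xcorr(psm: PSMRecord, policy: FilterPolicy) -> bool:
    """Charge-dependent Xcorr gate (inclusive at the threshold)."""
    return psm.xcorr >= policy.xcorr_threshold(psm.charge)


def longest_consecutive_run(indices: Iterable[int]) -> int:
    """Length of the longest run of consecutive integers; 0 for empty input."""
    s = sorted(set(indices))
    if not s:
        return 0
    best = cur = 1
    for prev, nxt in zip(s, s[1:]):
        cur = cur + 1 if nxt == prev + 1 else 1
        best = max(best, cur)
    return best


def _ion_rule_ok(psm: PSMRecord, policy: FilterPolicy) -> bool:
    b_run = longest_consecutive_run(psm.b_ions)
    y_run = longest_consecutive_run(psm.y_ions)
    k = policy.min_consecutive_ions
    if policy.consecutive_ion_mode == "both_series":
        return b_run >= k and y_run >= k
    return b_run >= k or y_run >= k


def filter_psms(
    psms: Sequence[PSMRecord],
    policy: FilterPolicy,
    *,
    strict_paper_mode: bool = True,
) -> Tuple[List[PSMRecord], Dict[str, int]]:
    """Apply PSM-level gates, returning kept PSMs and a per-rule audit.

    In ``strict_paper_mode`` (default) only the Xcorr gate removes PSMs
    here; the length, consecutive-ion and occurrence rules are deferred to
    single-peptide protein acceptance in :func:`accept_proteins`, which is
    how the published procedure frames them.  With the flag off, all rules
    are applied to every PSM (a stricter generalization): the occurrence
    rule then counts, per (sample, peptide) pair, PSMs that survive the
    Xcorr/length/ion gates.

    The audit counts each rejected PSM once, under the first rule it fails
    (rule order: xcorr, length, ions, occurrence), and satisfies
    ``kept + sum(rejections) == len(psms)``.
    """
    audit = {"xcorr": 0, "length": 0, "ions": 0, "occurrence": 0, "kept": 0}
    survivors: List[PSMRecord] = []
    for psm in psms:
        if not passes_xcorr(psm, policy):
            audit["xcorr"] += 1
            continue
        if not strict_paper_mode:
            if len(psm.peptide) < policy.min_peptide_length:
                audit["length"] += 1
                continue
            if not _ion_rule_ok(psm, policy):
                audit["ions"] += 1
                continue
        survivors.append(psm)

    if strict_paper_mode:
        kept = survivors
    else:
        occ = Counter((p.sample_id, p.peptide) for p in survivors)
        kept = []
        for psm in survivors:
            if occ[(psm.sample_id, psm.peptide)] >= policy.min_occurrences_per_sample:
                kept.append(psm)
            else:
                audit["occurrence"] += 1
    audit["kept"] = len(kept)
    return kept, audit


def accept_proteins(
    psms_kept: Sequence[PSMRecord],
    policy: FilterPolicy,
    strict_paper_mode: bool = True,
) -> List[AcceptedProtein]:
    """Accept proteins from Xcorr-passing PSMs.

    Multi-peptide proteins (>= 2 unique peptide sequences) are accepted
    outright.  A single-peptide protein is accepted only if its peptide
    satisfies the length and consecutive-ion rules and, in at least one
    sample, occurs at least ``min_occurrences_per_sample`` times.  Accepted
    single-peptide proteins carry a flag marking that external sequence
    confirmation (a BLAST lookup) remains pending; no lookup is performed.

    When ``strict_paper_mode`` is off the caller is expected to have
    already applied all PSM-level rules via :func:`filter_psms`; acceptance
    then only requires a nonempty peptide set.
    """
    by_acc: Dict[str, List[PSMRecord]] = defaultdict(list)
    for psm in psms_kept:
        by_acc[psm.accession].append(psm)

    accepted: List[AcceptedProtein] = []
    for acc in sorted(by_acc):
        recs = by_acc[acc]
        peptides = {r.peptide for r in recs}
        single = len(peptides) == 1
        if single and strict_paper_mode:
            pep = next(iter(peptides))
            # at least one spectrum must exhibit the consecutive-ion series
            ok_ions = any(_ion_rule_ok(r, policy) for r in recs)
            per_sample = Counter(r.sample_id for r in recs)
            ok_occ = any(
                n >= policy.min_occurrences_per_sample for n in per_sample.values()
            )
            if not (ok_ions and ok_occ and len(pep) >= policy.min_peptide_length):
                continue
        spc = Counter(r.sample_id for r in recs)
        accepted.append(
            AcceptedProtein(
                accession=acc,
                unique_peptides=peptides,
                spc_by_sample=dict(spc),
                single_peptide_flag=single,
                blast_confirmation_pending=single,
            )
        )
    return accepted


def group_presence_filter(
    proteins: Sequence[AcceptedProtein],
    labels: Mapping[str, str],
    policy: FilterPolicy,
) -> List[AcceptedProtein]:
    """Keep proteins detected in >= 30% (by default) of one group's samples.

    Detection means spectral count >= 1; the requirement per group of size
    n is ``ceil(fraction * n)`` samples.  Raises if a counted sample has no
    group label.
    """
    import math

    group_sizes: Dict[str, int] = Counter(labels.values())
    kept: List[AcceptedProtein] = []
    for prot in proteins:
        present_by_group: Dict[str, int] = Counter()
        for sample, count in prot.spc_by_sample.items():
            if count <= 0:
                continue
            if sample not in labels:
                raise ValueError(
                    f"sample {sample!r} (protein {prot.accession}) has no group label"
                )
            present_by_group[labels[sample]] += 1
        ok = any(
            present_by_group[g] >= math.ceil(policy.min_group_presence_fraction * n)
            for g, n in group_sizes.items()
            if n > 0
        )
        if ok:
            kept.append(prot)
    return kept


def proteins_to_matrix(
    proteins: Sequence[AcceptedProtein],
    labels: Mapping[str, str],
    splits: Mapping[str, str] | None = None,
) -> SpectralCountMatrix:
    """Assemble accepted proteins into a proteins x samples count matrix.

    Samples are the keys of ``labels`` in insertion order, so samples with
    zero counts everywhere still appear as columns.
    """
    import numpy as np

    sample_ids = list(labels.keys())
    protein_ids = [p.accession for p in proteins]
    counts = np.zeros((len(protein_ids), len(sample_ids)), dtype=int)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, prot in enumerate(proteins):
        for sample, n in prot.spc_by_sample.items():
            counts[i, col[sample]] = n
    return SpectralCountMatrix(
        counts=counts,
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        group_of=dict(labels),
        split_of=dict(splits) if splits else {},
    )
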