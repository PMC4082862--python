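"""Identification filtering from peptide-spectrum matches.

Builds a tiny PSM set around the acceptance-rule boundaries and runs the
multistep filter: charge-dependent Xcorr gate, then single-peptide
credibility rules (length >= 7, three consecutive fragment ions, three
occurrences in one sample), then the 30% group-presence rule.
"""

from spcregress import (
    FilterPolicy,
    PSMRecord,
    accept_proteins,
    filter_psms,
    group_presence_filter,
)

policy = FilterPolicy()  # Xcorr 1.9/2.3/2.6 for z=2/3/>=4

psms = [
    # multi-peptide protein: accepted on the Xcorr gate alone
    PSMRecord("s1", "MULTI", "ACDEFGHIK", 2, 2.0, frozenset({1, 2, 3})),
    PSMRecord("s1", "MULTI", "MKLNPQRST", 3, 2.4),
    # single-peptide protein meeting every extra rule (3 occurrences in s1)
    *[PSMRecord("s1", "SINGLE_OK", "ACDEFGH", 2, 1.9, frozenset({2, 3, 4}))
      for _ in range(3)],
    # single peptide occurring only twice: rejected by the occurrence rule
    *[PSMRecord("s1", "SINGLE_RARE", "ACDEFGH", 2, 2.5, frozenset({1, 2, 3}))
      for _ in range(2)],
    # fails the Xcorr gate outright (z=3 needs 2.3)
    PSMRecord("s1", "LOW_XCORR", "ACDEFGHIK", 3, 2.2, frozenset({1, 2, 3})),
]

kept, audit = filter_psms(psms, policy)
print(f"PSMs in: {len(psms)}, past Xcorr gate: {len(kept)}, audit: {audit}")

accepted = accept_proteins(kept, policy)
for p in accepted:
    print(f"accepted {p.accession}: {len(p.unique_peptides)} unique peptide(s), "
          f"counts {p.spc_by_sample}, single-peptide={p.single_peptide_flag}")

# group-presence rule on a 2-sample-per-group design
labels = {"s1": "regression", "s2": "regression",
          "s3": "persistence", "s4": "persistence"}
final = group_presence_filter(accepted, labels, policy)
print(f"after 30% group-presence rule: {[p.accession for p in final]}")
# MULTI and SINGLE_OK survive: each is detected in 1 of 2 regression
# samples (>= ceil(0.3 * 2) = 1); SINGLE_RARE and LOW_XCORR never reach
# this stage.
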