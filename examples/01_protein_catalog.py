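"""Load the packaged catalog of identified proteins.

The package ships the 165-protein catalog of high-significance
identifications from the emulated study (accession, length, molecular
weight, description, sequence coverage).  Decimal commas in the printed
table are normalized at parse time.
"""

from spcregress import load_packaged_catalog

catalog = load_packaged_catalog()
print(f"catalog entries: {len(catalog)}")

znf = next(e for e in catalog if e.description == "Zinc finger protein 441")
print(f"ZNF441: accession {znf.accession}, {znf.n_aa} aa, "
      f"{znf.mw_da:.0f} Da, coverage {znf.coverage_pct}%")

smallest = min(catalog, key=lambda e: e.n_aa)
print(f"smallest protein: {smallest.description} ({smallest.n_aa} aa)")
# The catalog is the fixed protein universe the spectral-count matrices
# refer to; 165 is also the default width of the synthetic datasets.
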