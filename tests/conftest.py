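import numpy as np
import pytest

from spcregress import FilterPolicy, PSMRecord, SpectralCountMatrix


@pytest.fixture
def policy():
    return FilterPolicy()


@pytest.fixture
def toy_matrix():
    """3 proteins x 4 samples, two samples per group."""
    return SpectralCountMatrix(
        counts=np.array([[0, 2, 5, 1], [3, 0, 0, 0], [1, 1, 1, 1]]),
        protein_ids=["P1", "P2", "P3"],
        sample_ids=["r1", "r2", "p1", "p2"],
        group_of={"r1": "regression", "r2": "regression",
                  "p1": "persistence", "p2": "persistence"},
        split_of={"r1": "learning", "r2": "validation",
                  "p1": "learning", "p2": "validation"},
    )


def make_psm(sample="s1", accession="A", peptide="ACDEFGH", charge=2, xcorr=2.5,
             b_ions=(), y_ions=()):
    return PSMRecord(
        sample_id=sample, accession=accession, peptide=peptide, charge=charge,
        xcorr=xcorr, b_ions=frozenset(b_ions), y_ions=frozenset(y_ions),
    )


def random_psms(rng, n=50, n_proteins=8, n_samples=3):
    """Random PSM instances straddling every rule boundary."""
    peptides = ["ACDEFG", "ACDEFGH", "ACDEFGHIKLMN"]
    ion_sets = [frozenset(), frozenset({1, 3, 5}), frozenset({2, 3, 4}),
                frozenset({1, 2, 3, 4})]
    out = []
    for _ in range(n):
        pep = peptides[rng.integers(len(peptides))]
        nmax = len(pep) - 1
        ions_b = frozenset(i for i in ion_sets[rng.integers(len(ion_sets))] if i <= nmax)
        ions_y = frozenset(i for i in ion_sets[rng.integers(len(ion_sets))] if i <= nmax)
        out.append(
            PSMRecord(
                sample_id=f"s{rng.integers(n_samples) + 1}",
                accession=f"P{rng.integers(n_proteins) + 1}",
                peptide=pep,
                charge=int(rng.integers(1, 6)),
                xcorr=float(rng.uniform(1.5, 3.0)),
                b_ions=ions_b,
                y_ions=ions_y,
            )
        )
    return out
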