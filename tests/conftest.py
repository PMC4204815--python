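import pytest

from plastomark import Alignment, build_consensus_pair
from plastomark.synthetic_data import (
    conserved_alignment, plant_substitutions, plant_gaps,
)


@pytest.fixture
def tiny_alignment():
    return Alignment(
        ids=["a", "b", "c"],
        rows=["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAC"],
    )


@pytest.fixture
def conserved600():
    """5 identical 600-column rows (deterministic background)."""
    return conserved_alignment(n_rows=5, length=600, seed=11)


@pytest.fixture
def consensus600(conserved600):
    return build_consensus_pair(conserved600)


def make_block_fixture(n_snps, extra_ambig=0, gap_run=0, *,
                       length=600, window_start=150, seed=11):
    """A conserved 5-row alignment with planted ambiguity confined to the
    300-column window starting at ``window_start``:

    * ``n_snps`` isolated substitution columns spaced 12 apart — each is a
      qualifying flanked SNP;
    * ``extra_ambig`` isolated single-row gap columns spaced 2 apart —
      ambiguous (divergent) columns that are never SNPs;
    * an optional run of ``gap_run`` consecutive gap columns.
    """
    a = conserved_alignment(n_rows=5, length=length, seed=seed)
    cursor = window_start + 8
    snp_cols = []
    for _ in range(n_snps):
        snp_cols.append(cursor)
        cursor += 12
    cursor += 5  # keep extras clear of the last SNP's flank
    gap_cols = []
    for _ in range(extra_ambig):
        gap_cols.append(cursor)
        cursor += 2
    cursor += 6
    run_cols = list(range(cursor, cursor + gap_run))
    cursor += gap_run + 6
    if cursor > window_start + 300:
        raise ValueError("fixture does not fit inside the window")
    a = plant_substitutions(a, snp_cols)
    a = plant_gaps(a, gap_cols + run_cols)
    return a
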