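import pytest

from varfunc import FamilyModel, MultipleAlignment, full_window, simulate_family


def make_msa(rows: list[str], query_index: int = 0, ids: list[str] | None = None):
    if ids is None:
        ids = [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(ids=ids, rows=rows, query_index=query_index)


@pytest.fixture
def two_block_window():
    """Planted two-subfamily family at conservation 1.0 (10 rows each),
    viewed as a single full-alignment window."""
    model = FamilyModel(
        n_subfamilies=2, rows_per_subfamily=10, width=30,
        conservation=1.0, seed=42,
    )
    msa, truth = simulate_family(model)
    return full_window(msa), truth
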