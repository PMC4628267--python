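"""Alignment handling: reading, redundancy removal, column filtering, and
selection of the alignment region surrounding a variant.

The classification pipeline never scores a variant against the full homolog
alignment.  Instead the alignment is cleaned (near-identical sequences and
gap-dominated columns removed) and a window of columns around the variant is
cut out; subfamily clustering and profile-HMM scoring operate on that window.
Processing order is fixed: redundancy removal, column filtering, region
selection, empty-row removal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = set(AMINO_ACIDS)


class MsaError(ValueError):
    """Raised for malformed alignments or inconsistent variant specs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """A single amino-acid substitution on the query sequence.

    ``position`` is 1-based on the *ungapped* query; ``wt_residue`` must match
    the query residue found there (checked by :func:`map_variant_to_column`).
    """

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self) -> None:
        if self.wt_residue not in ALPHABET or self.mut_residue not in ALPHABET:
            raise MsaError(
                f"variant residues must be one of the 20 amino acids: "
                f"{self.wt_residue}{self.position}{self.mut_residue}"
            )
        if self.wt_residue == self.mut_residue:
            raise MsaError("wild-type and mutant residues must differ")
        if self.position < 1:
            raise MsaError("variant position must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "VariantSpec":
        """Parse ``"A95E"`` notation (WT residue, position, mutant residue)."""
        text = text.strip()
        if len(text) < 3:
            raise MsaError(f"cannot parse variant {text!r}")
        wt, pos, mut = text[0], text[1:-1], text[-1]
        if not pos.isdigit():
            raise MsaError(f"cannot parse variant {text!r}")
        return cls(wt.upper(), int(pos), mut.upper())

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


@dataclass
class MultipleAlignment:
    """Rows of aligned residues/gaps with one designated query (wild-type) row."""

    ids: list[str]
    rows: list[str]
    query_index: int

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError("empty alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise MsaError("alignment rows have unequal widths")
        if len(set(self.ids)) != len(self.ids):
            raise MsaError("duplicate sequence ids in alignment")
        if not (0 <= self.query_index < len(self.rows)):
            raise MsaError("query index out of range")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    def ungapped(self, row_index: int) -> str:
        return self.rows[row_index].replace(GAP, "")


@dataclass
class AlignmentWindow:
    """A contiguous column range of an alignment, holding the variant column.

    ``kept_rows`` indexes rows of ``source`` that are not all-gap inside the
    window; the query row is always kept.
    """

    source: MultipleAlignment
    first_column: int
    last_column: int       # inclusive
    variant_column: int    # column index in `source`
    kept_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.first_column <= self.variant_column <= self.last_column):
            raise MsaError("variant column outside window")
        if not self.kept_rows:
            self.kept_rows = [
                i for i, r in enumerate(self.source.rows)
                if set(r[self.first_column : self.last_column + 1]) != {GAP}
            ]
        if self.source.query_index not in self.kept_rows:
            raise MsaError("window lost the query row")

    @property
    def width(self) -> int:
        return self.last_column - self.first_column + 1

    @property
    def n_rows(self) -> int:
        return len(self.kept_rows)

    @property
    def ids(self) -> list[str]:
        return [self.source.ids[i] for i in self.kept_rows]

    @property
    def rows(self) -> list[str]:
        a, b = self.first_column, self.last_column + 1
        return [self.source.rows[i][a:b] for i in self.kept_rows]

    @property
    def query_index(self) -> int:
        return self.kept_rows.index(self.source.query_index)

    @property
    def variant_offset(self) -> int:
        """Variant column as an offset inside the window."""
        return self.variant_column - self.first_column

    def query_region_sequence(self) -> str:
        """The query's ungapped residues inside the window (the scored wild type)."""
        return self.rows[self.query_index].replace(GAP, "")

    def variant_residue_index(self) -> int:
        """Index of the variant residue within :meth:`query_region_sequence`."""
        q = self.rows[self.query_index]
        off = self.variant_offset
        if q[off] == GAP:
            raise MsaError("query is gapped at the variant column")
        return sum(1 for c in q[:off] if c != GAP)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _normalise(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path_or_handle, query_id: str, fmt: str = "fasta") -> MultipleAlignment:
    """Read an aligned FASTA or Stockholm file into a :class:`MultipleAlignment`.

    ``fmt`` is any alignment format Biopython understands ("fasta",
    "stockholm", ...). ``'.'`` gap characters are normalised to ``'-'``.
    """
    aln = AlignIO.read(path_or_handle, fmt)
    ids = [rec.id for rec in aln]
    rows = [_normalise(str(rec.seq)) for rec in aln]
    try:
        qi = ids.index(query_id)
    except ValueError:
        raise MsaError(f"query id {query_id!r} not found in alignment") from None
    return MultipleAlignment(ids=ids, rows=rows, query_index=qi)


def write_alignment(msa: MultipleAlignment, handle_or_path) -> None:
    """Write an alignment as aligned FASTA."""
    text = "".join(f">{i}\n{r}\n" for i, r in zip(msa.ids, msa.rows))
    if hasattr(handle_or_path, "write"):
        handle_or_path.write(text)
    else:
        with open(handle_or_path, "w") as fh:
            fh.write(text)


def alignment_from_text(fasta_text: str, query_id: str) -> MultipleAlignment:
    return read_alignment(io.StringIO(fasta_text), query_id, "fasta")


# ---------------------------------------------------------------------------
# processing stages
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where both rows are non-gap.

    Returns 0 when the rows have no ungapped overlap.
    """
    both = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)


def remove_redundant(msa: MultipleAlignment, identity_threshold: float = 0.95) -> MultipleAlignment:
    """Drop near-duplicate rows: of any pair whose identity exceeds the
    threshold, the row with fewer non-gap residues is discarded (ties: the
    later row in input order).  The query row is never discarded.

    Greedy in input order: each row is compared against already-retained rows.
    """
    if not 0 < identity_threshold <= 1:
        raise MsaError("identity threshold must be in (0, 1]")
    keep: list[int] = []
    for i in range(msa.n_rows):
        drop_i = False
        for j in list(keep):
            ident = pairwise_identity(msa.rows[i], msa.rows[j])
            if ident <= identity_threshold:
                continue
            len_i = len(msa.ungapped(i))
            len_j = len(msa.ungapped(j))
            # decide which of the redundant pair goes; query is immune
            if i == msa.query_index:
                keep.remove(j)
            elif j == msa.query_index:
                drop_i = True
            elif len_i < len_j or (len_i == len_j):
                drop_i = True   # shorter, or tie -> later row goes
            else:
                keep.remove(j)
            if drop_i:
                break
        if not drop_i:
            keep.append(i)
    return MultipleAlignment(
        ids=[msa.ids[i] for i in keep],
        rows=[msa.rows[i] for i in keep],
        query_index=keep.index(msa.query_index),
    )


def filter_columns(
    msa: MultipleAlignment, max_gap_fraction: float = 0.99
) -> tuple[MultipleAlignment, dict[int, int]]:
    """Remove gap-dominated columns; keep a column iff its gap fraction is
    <= ``max_gap_fraction``.  Returns the filtered alignment and a map from
    old to new column indices (removed columns absent from the map).
    """
    if not 0 <= max_gap_fraction <= 1:
        raise MsaError("max gap fraction must be in [0, 1]")
    n = msa.n_rows
    keep_cols = [
        c for c in range(msa.width)
        if sum(r[c] == GAP for r in msa.rows) / n <= max_gap_fraction
    ]
    if not keep_cols:
        raise MsaError("no informative columns")
    col_map = {old: new for new, old in enumerate(keep_cols)}
    rows = ["".join(r[c] for c in keep_cols) for r in msa.rows]
    return (
        MultipleAlignment(ids=list(msa.ids), rows=rows, query_index=msa.query_index),
        col_map,
    )


def map_variant_to_column(msa: MultipleAlignment, variant: VariantSpec) -> int:
    """Locate the alignment column of the variant: the column whose query
    residue is the ``position``-th non-gap character, checking that residue
    equals the stated wild type.
    """
    q = msa.query_row
    seen = 0
    for col, ch in enumerate(q):
        if ch == GAP:
            continue
        seen += 1
        if seen == variant.position:
            if ch != variant.wt_residue:
                raise MsaError(
                    f"wild-type residue mismatch at position {variant.position}: "
                    f"query has {ch}, variant says {variant.wt_residue}"
                )
            return col
    raise MsaError(
        f"variant position {variant.position} beyond query length {seen}"
    )


def select_region(
    msa: MultipleAlignment,
    variant_column: int,
    min_width: int = 10,
    extension_gap_fraction: float = 0.10,
) -> AlignmentWindow:
    """Cut the window of columns around the variant used for scoring.

    Extension alternates left first, then right, one column at a time, and in
    the primary phase passes only through columns where the query is non-gap
    (keeping the query contiguous).  If both directions are blocked before the
    window reaches ``min_width``, a secondary phase continues through columns
    whose overall gap fraction is below ``extension_gap_fraction``.  Extension
    clamps at the alignment edges; rows that are all-gap inside the final
    window are dropped (the query row is always retained).
    """
    if min_width < 1:
        raise MsaError("min_width must be >= 1")
    if not (0 <= variant_column < msa.width):
        raise MsaError("variant column out of range")

    q = msa.query_row
    n = msa.n_rows

    def gap_frac(col: int) -> float:
        return sum(r[col] == GAP for r in msa.rows) / n

    def passable(col: int, secondary: bool) -> bool:
        if secondary:
            return gap_frac(col) < extension_gap_fraction
        return q[col] != GAP

    first = last = variant_column
    for secondary in (False, True):
        blocked_left = blocked_right = False
        while (last - first + 1) < min_width and not (blocked_left and blocked_right):
            if not blocked_left:                      # left first
                if first > 0 and passable(first - 1, secondary):
                    first -= 1
                else:
                    blocked_left = True
            if (last - first + 1) >= min_width:
                break
            if not blocked_right:
                if last < msa.width - 1 and passable(last + 1, secondary):
                    last += 1
                else:
                    blocked_right = True
        if (last - first + 1) >= min_width:
            break

    return AlignmentWindow(
        source=msa, first_column=first, last_column=last,
        variant_column=variant_column,
    )


def full_window(msa: MultipleAlignment, variant_column: int = 0) -> AlignmentWindow:
    """The whole alignment viewed as one window (useful for clustering an
    alignment independently of any variant)."""
    return AlignmentWindow(
        source=msa, first_column=0, last_column=msa.width - 1,
        variant_column=variant_column,
    )


def prepare_window(
    msa: MultipleAlignment,
    variant: VariantSpec,
    identity_threshold: float = 0.95,
    max_gap_fraction: float = 0.99,
    min_width: int = 10,
    extension_gap_fraction: float = 0.10,
) -> AlignmentWindow:
    """Full processing chain for one variant: redundancy removal, column
    filtering, variant mapping, region selection."""
    msa2 = remove_redundant(msa, identity_threshold)
    msa3, _ = filter_columns(msa2, max_gap_fraction)
    col = map_variant_to_column(msa3, variant)
    return select_region(msa3, col, min_width, extension_gap_fraction)
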