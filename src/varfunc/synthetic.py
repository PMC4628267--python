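"""Synthetic protein families with planted variants of known functional
outcome.

The generator emulates the premise behind subfamily-based variant scoring: a
homolog family that splits into conserved subfamilies, each an implicit
carrier of a distinct function.  Columns come in three kinds, interleaved
round-robin along the alignment so any scoring window sees all three:

* family-conserved columns — one residue shared by every subfamily;
* signature columns — one position, a distinct conserved residue per
  subfamily (these separate the subfamilies);
* variable columns — a two-residue pool (R_a, R_b): every non-target
  subfamily is conserved at R_a, while the target subfamily mixes R_a and
  R_b evenly, so the column carries no information about the target's own
  function.

Each planted variant type then has a clean score geometry: LoF mutates a
family-conserved column to a residue absent everywhere; SoF mutates a target
signature column to another subfamily's signature residue; GoF mutates a
variable column from R_b to R_a (the residue the other subfamilies keep);
CoF mutates a variable column from R_a to R_b, a residue already common at
that column within the target subfamily.  Alignments are gap-free and
deterministic given the model seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import AMINO_ACIDS, MultipleAlignment, VariantSpec


class SyntheticError(ValueError):
    pass


@dataclass
class FamilyModel:
    n_subfamilies: int = 3
    rows_per_subfamily: int = 12
    width: int = 40
    conservation: float = 0.95
    seed: int = 0

    family_conserved_columns: list[int] = field(default_factory=list)
    signature_columns: list[int] = field(default_factory=list)
    variable_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.conservation <= 1:
            raise SyntheticError("conservation must be in [0, 1]")
        if self.n_subfamilies < 1 or self.rows_per_subfamily < 1:
            raise SyntheticError("need at least one subfamily with one row")
        if self.n_subfamilies > 18:
            raise SyntheticError("too many subfamilies for distinct signature residues")
        if not self.family_conserved_columns and not self.signature_columns:
            self.family_conserved_columns = [c for c in range(self.width) if c % 3 == 0]
            self.signature_columns = [c for c in range(self.width) if c % 3 == 1]
            self.variable_columns = [c for c in range(self.width) if c % 3 == 2]
        needed = len(self.family_conserved_columns) + len(self.signature_columns)
        if self.width < needed or self.width < 3:
            raise SyntheticError(
                "width too small for the requested conserved + signature columns"
            )
        if set(self.family_conserved_columns) & set(self.signature_columns):
            raise SyntheticError("signature columns overlap family-conserved columns")

    # --- deterministic consensus layout -----------------------------------

    def _consensus(self):
        """Per-column residue plan, drawn once from the model seed.

        Returns (family_res, signature_res, pools): family_res[col] for
        conserved columns; signature_res[col][subfamily]; pools[col] =
        (R_a, R_b) for variable columns.
        """
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        aa = list(AMINO_ACIDS)
        family_res = {c: aa[rng.integers(20)] for c in self.family_conserved_columns}
        signature_res = {
            c: list(rng.choice(aa, size=self.n_subfamilies, replace=False))
            for c in self.signature_columns
        }
        pools = {
            c: tuple(rng.choice(aa, size=2, replace=False))
            for c in self.variable_columns
        }
        return family_res, signature_res, pools


def simulate_family(model: FamilyModel) -> tuple[MultipleAlignment, list[int]]:
    """Draw the alignment; returns it with the ground-truth subfamily labels.

    Each row emits, per column, the relevant consensus residue with
    probability ``conservation`` and otherwise a uniform draw from the
    remaining residues.  The query is the first row of subfamily 0.
    """
    family_res, signature_res, pools = model._consensus()
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 202]))
    aa = list(AMINO_ACIDS)
    rows, ids, labels = [], [], []
    for s in range(model.n_subfamilies):
        for r in range(model.rows_per_subfamily):
            chars = []
            for c in range(model.width):
                if c in family_res:
                    cons = family_res[c]
                elif c in signature_res:
                    cons = signature_res[c][s]
                else:
                    ra, rb = pools[c]
                    if s == 0:
                        # target subfamily: even two-residue mixture, no
                        # consensus of its own at variable columns
                        chars.append(ra if rng.random() < 0.5 else rb)
                        continue
                    cons = ra
                if rng.random() < model.conservation:
                    chars.append(cons)
                else:
                    others = [a for a in aa if a != cons]
                    chars.append(others[rng.integers(19)])
            rows.append("".join(chars))
            ids.append(f"sf{s}_r{r}")
            labels.append(s)
    return (
        MultipleAlignment(ids=ids, rows=rows, query_index=0),
        labels,
    )


PLANT_KINDS = ("LoF", "GoF", "SoF", "CoF")


def plant_variant(model: FamilyModel, kind: str) -> tuple[VariantSpec, str]:
    """Choose a substitution on the query whose expected functional outcome
    is ``kind``; returns the variant and its expected label.

    The alignment is gap-free, so the 1-based variant position equals
    column + 1.  Raises if the model geometry cannot host the request.
    """
    if kind not in PLANT_KINDS:
        raise SyntheticError(f"unknown variant kind {kind!r}")
    if kind in ("GoF", "SoF") and model.n_subfamilies < 2:
        raise SyntheticError(f"{kind} plant needs at least 2 subfamilies")
    msa, _ = simulate_family(model)
    query = msa.query_row
    family_res, signature_res, pools = model._consensus()

    if kind == "LoF":
        for c in model.family_conserved_columns:
            if query[c] != family_res[c]:
                continue
            present = {row[c] for row in msa.rows}
            absent = [a for a in AMINO_ACIDS if a not in present]
            if absent:
                return VariantSpec(query[c], c + 1, absent[0]), "LoF"
        raise SyntheticError("no family-conserved column supports a LoF plant")

    if kind == "SoF":
        for c in model.signature_columns:
            if query[c] == signature_res[c][0]:
                return VariantSpec(query[c], c + 1, signature_res[c][1]), "SoF"
        raise SyntheticError("query carries no target signature residue")

    if kind == "GoF":
        for c in model.variable_columns:
            ra, rb = pools[c]
            if query[c] == rb:
                return VariantSpec(rb, c + 1, ra), "GoF"
        raise SyntheticError("no variable column supports a GoF plant")

    # CoF
    for c in model.variable_columns:
        ra, rb = pools[c]
        if query[c] == ra:
            return VariantSpec(ra, c + 1, rb), "CoF"
    raise SyntheticError("no variable column supports a CoF plant")


def write_family(model: FamilyModel, fasta_path, truth_path,
                 variants: list[tuple[VariantSpec, str]] | None = None) -> None:
    """Write the simulated alignment as aligned FASTA plus a truth TSV
    (variant, planted label) and the subfamily map."""
    from .msa import write_alignment

    msa, labels = simulate_family(model)
    write_alignment(msa, fasta_path)
    with open(truth_path, "w") as fh:
        for variant, label in variants or []:
            fh.write(f"{variant}\t{label}\n")
        for sid, lab in zip(msa.ids, labels):
            fh.write(f"#subfamily\t{sid}\t{lab}\n")
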