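"""Per-subfamily profile hidden Markov models and the variant damage score.

Each cluster of the alignment window is summarised as a profile HMM with
match, insert and delete states (match columns are those with gap fraction at
or below 0.5; Laplace pseudocounts on emissions and transitions).  A sequence
is scored by the forward algorithm in global mode as a log2-odds bit score
against a uniform background.  The variant score compares the wild-type and
the mutant region sequence against one model: by default the ratio of their
bit scores, optionally their difference — either way, larger means the mutant
fits this subfamily worse than the wild type does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .msa import AMINO_ACIDS, GAP, AlignmentWindow, VariantSpec
from .clustering import ClusterPartition

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_LOG2E = np.log2(np.e)


class HmmError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """A match/insert/delete profile HMM over the 20 amino acids.

    Node ``j`` (1..n_match) has a match state M_j and delete state D_j;
    insert states I_j sit between nodes (j = 0..n_match).  Transition arrays
    are indexed by source node with successor order (match, insert, delete).
    """

    match_emissions: np.ndarray        # (n_match, 20)
    insert_emissions: np.ndarray       # (n_match + 1, 20)
    t_from_match: np.ndarray           # (n_match + 1, 3); row 0 = begin
    t_from_insert: np.ndarray          # (n_match + 1, 3)
    t_from_delete: np.ndarray          # (n_match + 1, 3); rows 1..n_match used
    background: np.ndarray = field(default_factory=lambda: np.full(20, 1 / 20))

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        for name, arr in (
            ("match emissions", self.match_emissions),
            ("insert emissions", self.insert_emissions),
            ("match transitions", self.t_from_match),
            ("insert transitions", self.t_from_insert),
            ("background", self.background[None, :]),
        ):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=tol):
                raise HmmError(f"{name} rows do not sum to 1")
        if not np.allclose(self.t_from_delete[1:].sum(axis=1), 1.0, atol=tol):
            raise HmmError("delete transitions do not sum to 1")
        if self.n_match < 1:
            raise HmmError("need at least one match state")


def build_profile(
    window: AlignmentWindow,
    cluster_rows: list[int],
    pseudocount: float = 1.0,
    match_gap_threshold: float = 0.5,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from one cluster of window rows.

    Columns whose gap fraction within the cluster is <= ``match_gap_threshold``
    become match states.  Emissions are (count + pseudocount) / (n + 20 *
    pseudocount); transitions are estimated from each row's observed state
    path with the same pseudocount per successor.
    """
    if len(cluster_rows) < 2:
        raise HmmError("subfamily too small: clusters of size 1 cannot seed a profile")
    if pseudocount <= 0:
        raise HmmError("pseudocount must be > 0")
    rows = window.rows
    seqs = [rows[i] for i in cluster_rows]
    n = len(seqs)
    width = window.width

    match_cols = [
        c for c in range(width)
        if sum(s[c] == GAP for s in seqs) / n <= match_gap_threshold
    ]
    if not match_cols:
        raise HmmError("cluster has no match-quality columns")
    m = len(match_cols)

    me = np.full((m, 20), pseudocount)
    ie = np.full((m + 1, 20), pseudocount)
    tm = np.full((m + 1, 3), pseudocount)
    ti = np.full((m + 1, 3), pseudocount)
    td = np.full((m + 1, 3), pseudocount)

    node_of_col = {c: j for j, c in enumerate(match_cols)}   # 0-based node-1
    for s in seqs:
        state, node = "M", 0          # begin treated as M_0
        for c in range(width):
            ch = s[c]
            if c in node_of_col:
                j = node_of_col[c] + 1
                if ch == GAP:
                    nxt = "D"
                else:
                    nxt = "M"
                    me[j - 1, _AA_INDEX[ch]] += 1
                {"M": tm, "I": ti, "D": td}[state][node, "MID".index(nxt)] += 1
                state, node = nxt, j
            elif ch != GAP:           # insert column residue
                ie[node, _AA_INDEX[ch]] += 1
                {"M": tm, "I": ti, "D": td}[state][node, 1] += 1
                state = "I"
        # transition into the end state, folded into the match slot
        {"M": tm, "I": ti, "D": td}[state][node, 0] += 1

    hmm = ProfileHMM(
        match_emissions=me / me.sum(axis=1, keepdims=True),
        insert_emissions=ie / ie.sum(axis=1, keepdims=True),
        t_from_match=tm / tm.sum(axis=1, keepdims=True),
        t_from_insert=ti / ti.sum(axis=1, keepdims=True),
        t_from_delete=td / td.sum(axis=1, keepdims=True),
        background=np.full(20, 1 / 20) if background is None else background,
    )
    hmm.validate()
    return hmm


def sequence_bitscore(hmm: ProfileHMM, sequence: str) -> float:
    """Forward-algorithm log-odds score of a sequence in bits.

    log2( P(sequence | profile, global mode) / P(sequence | background) ),
    computed in log space so arbitrarily long sequences stay finite.  The
    null model emits each residue independently from the background.
    """
    if not sequence:
        raise HmmError("empty sequence")
    try:
        x = np.array([_AA_INDEX[c] for c in sequence])
    except KeyError as e:
        raise HmmError(f"illegal residue {e.args[0]!r}") from None
    L, m = len(x), hmm.n_match

    with np.errstate(divide="ignore"):
        lme = np.log(hmm.match_emissions)          # (m, 20)
        lie = np.log(hmm.insert_emissions)         # (m+1, 20)
        ltm = np.log(hmm.t_from_match)             # (m+1, 3); row 0 = begin
        lti = np.log(hmm.t_from_insert)
        ltd = np.log(hmm.t_from_delete)

    NEG = -np.inf
    # index j=0 of fM is the (silent) begin state; D_0 does not exist.
    fM = np.full((L + 1, m + 1), NEG)
    fI = np.full((L + 1, m + 1), NEG)
    fD = np.full((L + 1, m + 1), NEG)
    fM[0, 0] = 0.0

    # i = 0: delete chain reachable from begin without emitting
    for i in range(0, L + 1):
        if i > 0:
            prevM, prevI, prevD = fM[i - 1], fI[i - 1], fD[i - 1]
            e_m = lme[:, x[i - 1]]                 # (m,)
            e_i = lie[:, x[i - 1]]                 # (m+1,)
            # M_j fed by M_{j-1}/I_{j-1}/D_{j-1} at i-1 (j-1 = 0 is begin)
            src = np.stack([
                prevM[:-1] + ltm[:-1, 0],
                prevI[:-1] + lti[:-1, 0],
                prevD[:-1] + ltd[:-1, 0],
            ])
            fM[i, 1:] = e_m + _lse(src, axis=0)
            # I_j fed by M_j/I_j/D_j at i-1
            src = np.stack([
                prevM + ltm[:, 1],
                prevI + lti[:, 1],
                prevD + ltd[:, 1],
            ])
            fI[i] = e_i + _lse(src, axis=0)
        # D_j fed by M_{j-1}/I_{j-1}/D_{j-1} at the same i (silent)
        for j in range(1, m + 1):
            fD[i, j] = _lse(np.array([
                fM[i, j - 1] + ltm[j - 1, 2],
                fI[i, j - 1] + lti[j - 1, 2],
                fD[i, j - 1] + ltd[j - 1, 2],
            ]))

    # end state reached from M_m / I_m / D_m through their "advance" slot
    log_p = _lse(np.array([
        fM[L, m] + ltm[m, 0],
        fI[L, m] + lti[m, 0],
        fD[L, m] + ltd[m, 0],
    ]))
    log_null = float(np.log(hmm.background[x]).sum())
    return float((log_p - log_null) * _LOG2E)


def _lse(a: np.ndarray, axis=None):
    with np.errstate(invalid="ignore"):
        return logsumexp(a, axis=axis)


# ---------------------------------------------------------------------------
# variant scoring
# ---------------------------------------------------------------------------

def hmmvar_score(
    hmm: ProfileHMM, wild: str, mutant: str, mode: str = "ratio"
) -> float:
    """Damage score of a substitution against one subfamily profile.

    ratio mode: bitscore(wild) / bitscore(mutant); difference mode:
    bitscore(wild) - bitscore(mutant).  Larger means the mutant fits this
    subfamily worse than the wild type does; values below the neutral fixed
    point (1 for ratio, 0 for difference) mean the mutant fits better.
    """
    if wild == mutant:
        raise HmmError("wild-type and mutant sequences are identical")
    diffs = sum(a != b for a, b in zip(wild, mutant))
    if len(wild) != len(mutant) or diffs != 1:
        raise HmmError("sequences must differ at exactly one position")
    bw = sequence_bitscore(hmm, wild)
    bm = sequence_bitscore(hmm, mutant)
    if mode == "difference":
        return bw - bm
    if mode == "ratio":
        if bm == 0.0:
            raise HmmError("undefined ratio: mutant bit score is zero")
        return bw / bm
    raise HmmError(f"unknown score mode {mode!r}")


@dataclass
class VariantScoreSet:
    """Scores of one variant against every eligible cluster profile."""

    per_cluster_score: dict[int, float]
    target_score: float | None
    min_other_score: float | None
    argmin_cluster: int | None
    no_call: bool
    mode_used: str
    wild: str = ""
    mutant: str = ""


def score_variant_across_clusters(
    window: AlignmentWindow,
    partition: ClusterPartition,
    variant: VariantSpec,
    significance_floor: float = 0.0,
    mode: str = "ratio",
    pseudocount: float = 1.0,
    match_gap_threshold: float = 0.5,
) -> VariantScoreSet:
    """Build one profile per eligible cluster (size > 1) and score the
    wild-type vs mutant window sequence against each.

    ``target_score`` is the score against the query's own cluster (label 0);
    ``min_other_score`` the minimum over the other eligible clusters.  When
    every wild and mutant bit score falls below ``significance_floor`` the
    result is flagged ``no_call``.  If ratio mode hits a zero-bit-score
    denominator for any cluster, all clusters are rescored in difference mode
    so the scores stay comparable (``mode_used`` records this).
    """
    eligible = partition.eligible_labels()
    if 0 not in eligible:
        raise HmmError("target cluster has size 1; cannot build its profile")

    wild = window.query_region_sequence()
    pos = window.variant_residue_index()
    if wild[pos] != variant.wt_residue:
        raise HmmError("wild-type residue mismatch at variant column")
    mutant = wild[:pos] + variant.mut_residue + wild[pos + 1:]

    hmms = {
        label: build_profile(window, partition.members(label),
                             pseudocount, match_gap_threshold)
        for label in eligible
    }
    bits = {
        label: (sequence_bitscore(h, wild), sequence_bitscore(h, mutant))
        for label, h in hmms.items()
    }
    no_call = all(
        bw < significance_floor and bm < significance_floor
        for bw, bm in bits.values()
    )

    def scores_with(m: str) -> dict[int, float]:
        out = {}
        for label, (bw, bm) in bits.items():
            if m == "ratio":
                if bm == 0.0:
                    raise HmmError("undefined ratio")
                out[label] = bw / bm
            else:
                out[label] = bw - bm
        return out

    mode_used = mode
    try:
        per = scores_with(mode)
    except HmmError:
        mode_used = "difference"
        per = scores_with("difference")

    others = {l: s for l, s in per.items() if l != 0}
    if others:
        argmin = min(others, key=lambda l: (others[l], l))
        min_other = others[argmin]
    else:
        argmin, min_other = None, None
    return VariantScoreSet(
        per_cluster_score=per,
        target_score=per[0],
        min_other_score=min_other,
        argmin_cluster=argmin,
        no_call=no_call,
        mode_used=mode_used,
        wild=wild,
        mutant=mutant,
    )


def write_region_fasta(scores: VariantScoreSet, variant: VariantSpec, handle_or_path) -> None:
    """Emit the scored wild-type and mutant window sequences as FASTA."""
    text = (
        f">wild_{variant}\n{scores.wild}\n"
        f">mutant_{variant}\n{scores.mutant}\n"
    )
    if hasattr(handle_or_path, "write"):
        handle_or_path.write(text)
    else:
        with open(handle_or_path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# profile IO (plain-text tabular dump)
# ---------------------------------------------------------------------------

def dump_profile(hmm: ProfileHMM, path) -> None:
    """Write a profile as a documented plain-text table (one block per
    parameter matrix, tab-separated, full float precision)."""
    blocks = {
        "MATCH_EMISSIONS": hmm.match_emissions,
        "INSERT_EMISSIONS": hmm.insert_emissions,
        "T_FROM_MATCH": hmm.t_from_match,
        "T_FROM_INSERT": hmm.t_from_insert,
        "T_FROM_DELETE": hmm.t_from_delete,
        "BACKGROUND": hmm.background[None, :],
    }
    with open(path, "w") as fh:
        fh.write(f"# profile HMM, n_match={hmm.n_match}, alphabet={AMINO_ACIDS}\n")
        for name, arr in blocks.items():
            fh.write(f">{name}\n")
            for row in np.atleast_2d(arr):
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_profile(path) -> ProfileHMM:
    blocks: dict[str, list[list[float]]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                current = line[1:]
                blocks[current] = []
            else:
                blocks[current].append([float(v) for v in line.split("\t")])
    hmm = ProfileHMM(
        match_emissions=np.array(blocks["MATCH_EMISSIONS"]),
        insert_emissions=np.array(blocks["INSERT_EMISSIONS"]),
        t_from_match=np.array(blocks["T_FROM_MATCH"]),
        t_from_insert=np.array(blocks["T_FROM_INSERT"]),
        t_from_delete=np.array(blocks["T_FROM_DELETE"]),
        background=np.array(blocks["BACKGROUND"][0]),
    )
    hmm.validate()
    return hmm
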