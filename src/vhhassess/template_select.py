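"""Pairwise global alignment, identity matrices and template-selection
scenarios for comparative modelling.

Four selection strategies are supported for a query against a library of
candidate templates:

``bestSeqIdTemp``
    the single template with the highest global sequence identity (the
    classical homology-modelling protocol);
``bestStructTemp``
    the single template structurally closest to the solved query (lowest
    C-alpha RMSD) — a theoretical upper bound, usable only in benchmarks;
``3bestSeqIdTemp``
    the three highest-identity templates jointly (multi-template mode),
    reported with their mean sequence identity (MSI);
``All``
    every candidate, ranked by identity.

Model-quality scores (e.g. DOPE, lower = better) are consumed as an external
input; :func:`select_best_model` only applies the ranking rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

SCENARIOS = ("bestSeqIdTemp", "bestStructTemp", "3bestSeqIdTemp", "All")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with affine gap penalties."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float
    aligned_column_pairs: tuple  # 1-based (a_index, b_index) of non-gap columns

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _identity_from_alignment(aln_a: str, aln_b: str) -> float:
    """Identities over alignment columns, terminal gap columns excluded."""
    n = len(aln_a)
    first, last = 0, n - 1
    while first < n and (aln_a[first] == "-" or aln_b[first] == "-"):
        first += 1
    while last >= 0 and (aln_a[last] == "-" or aln_b[last] == "-"):
        last -= 1
    if last < first:
        return 0.0
    cols = last - first + 1
    ident = sum(1 for a, b in zip(aln_a[first:last + 1], aln_b[first:last + 1])
                if a == b and a != "-")
    return 100.0 * ident / cols


def global_align(seq_a: str, seq_b: str, sub_matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment with affine gaps.

    ``gap_open`` is the penalty of the first residue of a gap and
    ``gap_extend`` of each subsequent one (Biopython's convention: a gap of
    length k costs gap_open + (k-1) * gap_extend).  Sequences may contain
    ``X`` for unknown residues.  The first optimal traceback in Biopython's
    deterministic enumeration order is returned.
    """
    for s in (seq_a, seq_b):
        if not s:
            raise ValueError("empty sequence")
        bad = set(s) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
    try:
        matrix = substitution_matrices.load(sub_matrix)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix: {sub_matrix!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    pairs = []
    ia = ib = 0
    for ca, cb in zip(sa, sb):
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if ca != "-" and cb != "-":
            pairs.append((ia, ib))
    return PairwiseAlignment(
        aligned_a=sa,
        aligned_b=sb,
        score=float(aln.score),
        identity_percent=_identity_from_alignment(sa, sb),
        aligned_column_pairs=tuple(pairs),
    )


def build_identity_matrix(sequences: dict, **align_kwargs) -> pd.DataFrame:
    """Symmetric pairwise identity matrix (percent) over an id -> sequence map."""
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident = global_align(sequences[a], sequences[b], **align_kwargs).identity_percent
            mat.loc[a, b] = mat.loc[b, a] = ident
    return mat


def mean_offdiagonal_identity(matrix: pd.DataFrame) -> float:
    """Mean of the off-diagonal entries of an identity matrix."""
    m = matrix.to_numpy(dtype=float)
    mask = ~np.eye(m.shape[0], dtype=bool)
    return float(m[mask].mean())


@dataclass
class ScenarioResult:
    """Templates chosen for one query under one selection scenario."""

    query_id: str
    scenario: str
    template_ids: list
    identity_percent: float  # SI for single template, MSI for multi
    best_model_id: str = None
    best_model_rmsd: float = None
    per_template_identity: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "scenario": self.scenario,
            "template_ids": list(self.template_ids),
            "identity_percent": self.identity_percent,
            "best_model_id": self.best_model_id,
            "best_model_rmsd": self.best_model_rmsd,
            "per_template_identity": dict(self.per_template_identity),
        }


def _ranked_candidates(query_id: str, matrix: pd.DataFrame, ascending: bool):
    if query_id not in matrix.index:
        raise KeyError(f"query {query_id!r} not in matrix")
    col = matrix.loc[query_id].drop(query_id)
    # stable sort on value with lexicographic id tie-break
    order = sorted(col.items(), key=lambda kv: ((kv[1] if ascending else -kv[1]), kv[0]))
    return [k for k, _ in order], dict(col)


def select_templates(query_id: str, identity_matrix: pd.DataFrame,
                     rmsd_matrix: pd.DataFrame = None,
                     scenario: str = "bestSeqIdTemp") -> ScenarioResult:
    """Apply one template-selection scenario for a query.

    ``identity_matrix`` (and, for ``bestStructTemp``, ``rmsd_matrix``) are
    symmetric DataFrames indexed by structure id.  Ties are broken by
    lexicographic id.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    by_ident, ident = _ranked_candidates(query_id, identity_matrix, ascending=False)

    if scenario == "bestSeqIdTemp":
        chosen = by_ident[:1]
    elif scenario == "bestStructTemp":
        if rmsd_matrix is None:
            raise ValueError("bestStructTemp requires an RMSD matrix")
        by_rmsd, _ = _ranked_candidates(query_id, rmsd_matrix, ascending=True)
        chosen = by_rmsd[:1]
    elif scenario == "3bestSeqIdTemp":
        if len(by_ident) < 3:
            raise ValueError("3bestSeqIdTemp needs at least 3 candidates")
        chosen = by_ident[:3]
    else:  # All
        chosen = by_ident

    si = float(np.mean([ident[t] for t in chosen]))
    return ScenarioResult(
        query_id=query_id,
        scenario=scenario,
        template_ids=chosen,
        identity_percent=si,
        per_template_identity={t: float(ident[t]) for t in chosen},
    )


def select_best_model(model_scores: dict) -> str:
    """Pick the model id with the minimum score (lower = better, as for
    DOPE); ties go to the lexicographically smallest id."""
    if not model_scores:
        raise ValueError("no scored models")
    items = [(k, float(v)) for k, v in model_scores.items()]
    if any(not np.isfinite(v) for _, v in items):
        raise ValueError("non-finite model score")
    return min(items, key=lambda kv: (kv[1], kv[0]))[0]


def redundancy_filter(identity_matrix: pd.DataFrame, threshold: float = 95.0) -> list:
    """Greedy redundancy pruning: scan ids in lexicographic order and keep
    an id only if its identity to every already-kept id is below the
    threshold (percent)."""
    kept = []
    for an_id in sorted(identity_matrix.index):
        if all(identity_matrix.loc[an_id, k] < threshold for k in kept):
            kept.append(an_id)
    return kept


def write_pir_alignment(query_id: str, alignments, template_refs, path,
                        query_sequence: str = None) -> None:
    """Write a PIR-dialect alignment file for comparative modelling.

    ``alignments`` is a list of :class:`PairwiseAlignment` objects, each
    aligning the query (as sequence A) to one template (as sequence B);
    ``template_refs`` maps template id -> (pdb_file, chain_id) descriptor
    info.  Multiple pairwise alignments are stacked on the query: template
    insertions relative to the query open gap columns in every other row.
    The query entry comes last, marked ``sequence``; templates are marked
    ``structureX``.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("need at least one alignment")
    template_ids = list(template_refs)
    if len(template_ids) != len(alignments):
        raise ValueError("one template reference per alignment required")

    queries = ["".join(c for c in a.aligned_a if c != "-") for a in alignments]
    if len(set(queries)) != 1:
        raise ValueError("inconsistent query sequence across alignments")
    if query_sequence is not None and queries[0] != query_sequence:
        raise ValueError("alignments do not de-gap to the given query sequence")
    query = queries[0]
    Lq = len(query)

    # per alignment: template residues before the first query residue,
    # paired with query position i (1..L), and inserted after position i
    blocks = []
    for a in alignments:
        segs = [[] for _ in range(Lq + 1)]  # segs[i] = template letters after query pos i
        paired = [None] * (Lq + 1)          # paired[i] = template letter at query pos i
        qpos = 0
        for ca, cb in zip(a.aligned_a, a.aligned_b):
            if ca == "-":
                segs[qpos].append(cb)
            else:
                qpos += 1
                paired[qpos] = cb
        blocks.append((paired, segs))

    insert_len = [max(len(b[1][i]) for b in blocks) for i in range(Lq + 1)]

    def render(paired, segs):
        out = []
        for i in range(Lq + 1):
            seg = "".join(segs[i])
            out.append(seg + "-" * (insert_len[i] - len(seg)))
            if i < Lq:
                out.append(paired[i + 1] if paired[i + 1] else "-")
        return "".join(out)

    rows = [render(*b) for b in blocks]
    qrow = "".join(
        "-" * insert_len[i] + (query[i] if i < Lq else "")
        for i in range(Lq + 1)
    )
    all_rows = rows + [qrow]
    for col in range(len(qrow)):
        if all(r[col] == "-" for r in all_rows):
            raise ValueError("gap-only alignment column")

    def wrap(s, width=75):
        return "\n".join(s[i:i + width] for i in range(0, len(s), width))

    with open(path, "w") as fh:
        for tid, row in zip(template_ids, rows):
            ref = template_refs[tid]
            pdb_file, chain = (ref if isinstance(ref, (tuple, list)) else (ref, "A"))
            fh.write(f">P1;{tid}\n")
            fh.write(f"structureX:{pdb_file}:FIRST:{chain}:LAST:{chain}::::\n")
            fh.write(wrap(row) + "*\n")
        fh.write(f">P1;{query_id}\n")
        fh.write(f"sequence:{query_id}:::::::0.00:0.00\n")
        fh.write(wrap(qrow) + "*\n")


def read_pir_alignment(path) -> dict:
    """Parse a PIR file back to an ordered {id: gapped_sequence} mapping."""
    entries = {}
    name, seq_lines = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">P1;"):
                if name is not None:
                    raise ValueError(f"entry {name} not '*'-terminated")
                name = line[4:].strip()
                seq_lines = []
                descriptor = False
            elif name is not None:
                if not descriptor:
                    descriptor = True  # one descriptor line follows the header
                    continue
                seq_lines.append(line)
                if line.endswith("*"):
                    entries[name] = "".join(seq_lines)[:-1].replace("\n", "")
                    name = None
    if name is not None:
        raise ValueError(f"entry {name} not '*'-terminated")
    return entries
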