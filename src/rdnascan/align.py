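"""Pairwise alignment primitives.

Protein alignment is Smith–Waterman (BLOSUM62, affine gaps) via
Biopython's C aligner. Nucleotide alignment uses edit-distance optimal
alignment (edlib) in two modes:

* ``glocal`` — the full query is aligned within the target (infix);
* ``local``  — glocal followed by trimming of terminal indel runs, so
  unmatched query ends do not count against identity or span.

All downstream decisions in the package are identity thresholds over
alignment columns, for which unit-cost edit-distance alignment and a
+match/−mismatch scoring scheme select the same alignments in the
near-identity regime this pipeline operates in (>80% identity).

Identity is defined as matches / alignment columns with gap columns in
the denominator; ``N`` and ``X`` never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqcore import Interval, NucSeq, ProtSeq, reverse_complement

@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment with identity bookkeeping.

    ``aligned_query``/``aligned_target`` are equal-length gapped strings.
    ``query_span``/``target_span`` are half-open 0-based intervals on the
    ungapped sequences covered by the alignment.
    """

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    query_span: Interval
    target_span: Interval
    #: characters that never count as a match: N for nucleotides,
    #: X (masked/unknown residue) for proteins
    ambiguous: frozenset = frozenset("N")

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("aligned strings must have equal length")

    @property
    def columns(self) -> int:
        return len(self.aligned_query)

    @property
    def matches(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_target)
            if a == b and a != "-" and a not in self.ambiguous
        )

    @property
    def identity_pct(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns

    @property
    def gap_runs(self) -> list[tuple[int, int, str]]:
        """(column_start, run_length, kind) for each gap run.

        kind is 'del' when the query has bases absent from the target
        (gap in target row) and 'ins' when the target has extra bases.
        """
        runs: list[tuple[int, int, str]] = []
        i = 0
        while i < self.columns:
            if self.aligned_query[i] == "-":
                j = i
                while j < self.columns and self.aligned_query[j] == "-":
                    j += 1
                runs.append((i, j - i, "ins"))
                i = j
            elif self.aligned_target[i] == "-":
                j = i
                while j < self.columns and self.aligned_target[j] == "-":
                    j += 1
                runs.append((i, j - i, "del"))
                i = j
            else:
                i += 1
        return runs


@lru_cache(maxsize=None)
def _protein_aligner(open_gap: float, extend_gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def protein_alignment_score(
    query: ProtSeq | str,
    target: ProtSeq | str,
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
) -> float:
    """Smith–Waterman score only (no traceback) — cheap frame triage."""
    q = query.residues if isinstance(query, ProtSeq) else query.rstrip("*")
    t = target.residues if isinstance(target, ProtSeq) else target.rstrip("*")
    if not q or not t:
        return 0.0
    return float(_protein_aligner(open_gap, extend_gap).score(q, t))


def local_align_protein(
    query: ProtSeq,
    target: ProtSeq,
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
) -> PairwiseAlignment | None:
    """Best Smith–Waterman local alignment under BLOSUM62 + affine gaps.

    Terminal stops are stripped before aligning. Returns ``None`` when no
    positive-scoring local alignment exists (e.g. disjoint alphabets).
    """
    q, t = query.residues, target.residues
    if not q or not t:
        raise ValueError("cannot align empty protein sequences")
    aligner = _protein_aligner(open_gap, extend_gap)
    if aligner.score(q, t) <= 0:
        return None
    aln = aligner.align(q, t)[0]
    qa, ta = str(aln[0]), str(aln[1])
    qs, ts = aln.aligned[0], aln.aligned[1]
    return PairwiseAlignment(
        query_id=query.id,
        target_id=target.id,
        aligned_query=qa,
        aligned_target=ta,
        score=float(aln.score),
        query_span=Interval(int(qs[0][0]), int(qs[-1][1])),
        target_span=Interval(int(ts[0][0]), int(ts[-1][1])),
        ambiguous=frozenset("X"),
    )


def _edlib_alignment(
    query: NucSeq | str,
    target: NucSeq | str,
    mode: str,
    k: int = -1,
) -> PairwiseAlignment | None:
    qseq = query.seq if isinstance(query, NucSeq) else query
    tseq = target.seq if isinstance(target, NucSeq) else target
    qid = query.id if isinstance(query, NucSeq) else "query"
    tid = target.id if isinstance(target, NucSeq) else "target"
    res = edlib.align(qseq, tseq, mode=mode, task="path", k=k)
    if res["editDistance"] < 0:
        return None
    t0, t1 = res["locations"][0]
    t1 += 1  # edlib end is inclusive
    nice = edlib.getNiceAlignment(res, qseq, tseq)
    return PairwiseAlignment(
        query_id=qid,
        target_id=tid,
        aligned_query=nice["query_aligned"],
        aligned_target=nice["target_aligned"],
        score=-float(res["editDistance"]),
        query_span=Interval(0, len(qseq)),
        target_span=Interval(t0, t1),
    )


def _trim_terminal_indels(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Drop leading/trailing gap runs, adjusting spans accordingly."""
    qa, ta = aln.aligned_query, aln.aligned_target
    n = len(qa)
    lo = 0
    while lo < n and (qa[lo] == "-" or ta[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (qa[hi - 1] == "-" or ta[hi - 1] == "-"):
        hi -= 1
    if lo == 0 and hi == n:
        return aln
    if hi <= lo:
        return PairwiseAlignment(
            aln.query_id, aln.target_id, "", "", aln.score,
            aln.query_span, aln.target_span, ambiguous=aln.ambiguous,
        )
    q_lead = sum(1 for c in qa[:lo] if c != "-")
    q_tail = sum(1 for c in qa[hi:] if c != "-")
    t_lead = sum(1 for c in ta[:lo] if c != "-")
    t_tail = sum(1 for c in ta[hi:] if c != "-")
    return PairwiseAlignment(
        aln.query_id,
        aln.target_id,
        qa[lo:hi],
        ta[lo:hi],
        aln.score,
        Interval(aln.query_span.start + q_lead, aln.query_span.end - q_tail),
        Interval(aln.target_span.start + t_lead, aln.target_span.end - t_tail),
        ambiguous=aln.ambiguous,
    )


def align_nucleotide(
    query: NucSeq | str,
    target: NucSeq | str,
    mode: str = "glocal",
    k: int = -1,
) -> PairwiseAlignment | None:
    """Edit-distance-optimal nucleotide alignment of query within target.

    ``glocal`` aligns the full query inside the target; ``local``
    additionally trims terminal indel runs so that partially-contained
    queries are scored only over their matched core. The operation is
    strand-naive: callers try both orientations. ``k`` bounds the edit
    distance (edlib semantics, -1 = unbounded); ``None`` is returned
    when no alignment within ``k`` exists.
    """
    if mode not in ("glocal", "local", "global"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    edlib_mode = "NW" if mode == "global" else "HW"
    aln = _edlib_alignment(query, target, edlib_mode, k=k)
    if aln is None:
        return None
    if mode == "local":
        aln = _trim_terminal_indels(aln)
    return aln


def best_strand_alignment(
    query: NucSeq,
    target: NucSeq,
    mode: str = "glocal",
    k: int = -1,
) -> tuple[PairwiseAlignment | None, str]:
    """Align query against both strands of target; return best + strand.

    The returned alignment is in the coordinates of the given target for
    '+' and of its reverse complement for '-'; the caller is responsible
    for mapping '-' spans back to forward coordinates when needed.
    """
    fwd = align_nucleotide(query, target, mode=mode, k=k)
    rc = NucSeq(target.id, reverse_complement(target.seq))
    rev = align_nucleotide(query, rc, mode=mode, k=k)
    if fwd is None and rev is None:
        return None, "+"
    if rev is None or (fwd is not None and fwd.score >= rev.score):
        return fwd, "+"
    return rev, "-"


def left_normalize(aligned_ref: str, aligned_alt: str) -> tuple[str, str]:
    """Shift gap runs maximally left (standard indel normalization).

    A gap run may move one column left when the base entering the run
    equals the base leaving it on the ungapped row, which preserves both
    implied sequences and every match/mismatch column while making indel
    placement in repeats and homopolymers deterministic.
    """
    rows = [list(aligned_ref), list(aligned_alt)]
    n = len(rows[0])
    changed = True
    while changed:
        changed = False
        for r in (0, 1):
            gapped, other = rows[r], rows[1 - r]
            i = 0
            while i < n:
                if gapped[i] != "-":
                    i += 1
                    continue
                j = i
                while j < n and gapped[j] == "-":
                    j += 1
                if (
                    i > 0
                    and gapped[i - 1] != "-"
                    and other[i - 1] != "-"
                    and other[j - 1] == other[i - 1]
                ):
                    gapped[i - 1], gapped[j - 1] = gapped[j - 1], gapped[i - 1]
                    changed = True
                i = j
    return "".join(rows[0]), "".join(rows[1])
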