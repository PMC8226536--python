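"""Affine-gap pairwise alignment (Gotoh), optionally banded.

This is the workhorse under homologous-locus discovery and the star
alignment used for discriminating-site detection. Scoring defaults are
blastn-like (match +2, mismatch -3, gap open -5 for the first gapped base,
gap extend -2 thereafter) so identities land on the same scale as a
megablast search.

The dynamic program is written once as a plain-Python/numpy kernel and
jit-compiled with numba when numba is importable; otherwise the identical
function body runs interpreted. Band limits are expressed as a corridor of
diagonals ``j - i`` covering both sequence ends, so a band of ``b`` allows
up to roughly ``b`` indels beyond the length difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

NEG = -(10**8)


def _gotoh(q, t, match, mismatch, gap_open, gap_extend, lo, hi, free_tb, free_te):
    m = q.shape[0]
    n = t.shape[0]
    H = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    PH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    H[0, 0] = 0
    jhi0 = n if hi >= n else hi
    for j in range(1, jhi0 + 1):
        if free_tb:
            H[0, j] = 0
            PH[0, j] = 3
        else:
            e_open = H[0, j - 1] + gap_open
            e_ext = E[0, j - 1] + gap_extend
            if e_open >= e_ext:
                E[0, j] = e_open
                PE[0, j] = 0
            else:
                E[0, j] = e_ext
                PE[0, j] = 1
            H[0, j] = E[0, j]
            PH[0, j] = 1
    for i in range(1, m + 1):
        if i <= -lo:
            f_open = H[i - 1, 0] + gap_open
            f_ext = F[i - 1, 0] + gap_extend
            if f_open >= f_ext:
                F[i, 0] = f_open
                PF[i, 0] = 0
            else:
                F[i, 0] = f_ext
                PF[i, 0] = 1
            H[i, 0] = F[i, 0]
            PH[i, 0] = 2
        jlo = i + lo
        if jlo < 1:
            jlo = 1
        jhi = i + hi
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            if q[i - 1] == t[j - 1]:
                best = H[i - 1, j - 1] + match
            else:
                best = H[i - 1, j - 1] + mismatch
            ptr = 0
            if E[i, j] > best:
                best = E[i, j]
                ptr = 1
            if F[i, j] > best:
                best = F[i, j]
                ptr = 2
            H[i, j] = best
            PH[i, j] = ptr
    return H, PH, PE, PF


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _gotoh = njit(cache=False)(_gotoh)
except Exception:  # pragma: no cover
    pass


@dataclass
class PairwiseAlignment:
    """Result of an affine alignment.

    ``ops`` is a per-column list over the alignment: ``M`` consumes one base
    of each sequence (match or mismatch), ``I`` consumes target only (gap in
    the query), ``D`` consumes query only (gap in the target).
    """

    score: int
    ops: str
    query_start: int  # 0-based half-open aligned ranges
    query_end: int
    target_start: int
    target_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def gap_runs(self, op: str) -> List[int]:
        """Lengths of maximal runs of *op* ('I' or 'D') in the alignment."""
        runs, cur = [], 0
        for o in self.ops:
            if o == op:
                cur += 1
            elif cur:
                runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        return runs

    def aligned_strings(self, query: str, target: str) -> Tuple[str, str]:
        qa, ta = [], []
        qi, tj = self.query_start, self.target_start
        for o in self.ops:
            if o == "M":
                qa.append(query[qi])
                ta.append(target[tj])
                qi += 1
                tj += 1
            elif o == "I":
                qa.append("-")
                ta.append(target[tj])
                tj += 1
            else:
                qa.append(query[qi])
                ta.append("-")
                qi += 1
        return "".join(qa), "".join(ta)


def affine_align(
    query: str,
    target: str,
    *,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
    band: Optional[int] = None,
    free_target_ends: bool = False,
    trim_query_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Align *query* against *target* with affine gap costs.

    With ``free_target_ends`` the target's leading/trailing overhang is not
    penalized (glocal mode, for fitting a query into a larger window). With
    ``band=None`` the full matrix is evaluated. ``trim_query_end_gaps``
    removes terminal ``D`` runs from the reported alignment — useful when a
    truncated query should not drag identity down with forced end gaps.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    m, n = len(q), len(t)
    if band is None:
        lo, hi = -m, n
    else:
        lo = min(0, n - m) - band
        hi = max(0, n - m) + band
    H, PH, PE, PF = _gotoh(
        q, t, match, mismatch, gap_open, gap_extend, lo, hi, free_target_ends, free_target_ends
    )
    if free_target_ends:
        jlo = max(0, m + lo)
        j_end = int(np.argmax(H[m, jlo : n + 1])) + jlo
    else:
        j_end = n
    score = int(H[m, j_end])
    # traceback
    ops_rev = []
    i, j = m, j_end
    state = 0  # 0=H 1=E 2=F
    while i > 0 or j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 3:  # free leading target gap
                break
            if p == 0:
                ops_rev.append("M")
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            p = PE[i, j]
            ops_rev.append("I")
            j -= 1
            if p == 0:
                state = 0
        else:
            p = PF[i, j]
            ops_rev.append("D")
            i -= 1
            if p == 0:
                state = 0
    ops = "".join(reversed(ops_rev))
    q_start, t_start = i, j
    if trim_query_end_gaps:
        lead = len(ops) - len(ops.lstrip("D"))
        trail = len(ops) - len(ops.rstrip("D"))
        if lead:
            q_start += lead
            ops = ops[lead:]
        if trail:
            m_new_end = m - trail
            ops = ops[: len(ops) - trail]
        else:
            m_new_end = m
    else:
        m_new_end = m
    matches = 0
    qi, tj = q_start, t_start
    for o in ops:
        if o == "M":
            if query[qi] == target[tj]:
                matches += 1
            qi += 1
            tj += 1
        elif o == "I":
            tj += 1
        else:
            qi += 1
    return PairwiseAlignment(
        score=score,
        ops=ops,
        query_start=q_start,
        query_end=m_new_end,
        target_start=t_start,
        target_end=tj,
        matches=matches,
        columns=len(ops),
    )
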