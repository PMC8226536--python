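"""Discovery and classification of cDNA-homologous genomic loci.

The search re-creates what a spliced-alignment web query does for a single
transcript: k-mer seeds on both strands, colinear chaining that tolerates
intron-sized gaps on the genomic side, and banded affine alignment of each
chained segment. A processed pseudogene chains as one contiguous segment;
the parent gene chains as one segment per exon with intron-sized jumps in
between. Per-hit identity is computed over aligned columns with
intron-scale gaps (>= ``g_intron``, the segment breaks) excluded, which
keeps the parent self-hit on the same identity scale as the intronless
copies.

Classification follows the textbook definition of a processed pseudogene:
an intronless copy, or one whose reading frame is broken, that does not
overlap the parent gene itself; an introns-plus-ORF-intact homolog is a
diverged paralog.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .align import affine_align
from .seqio import GeneModel, GenomicInterval, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class HomologySearchParams:
    """Tunables for the seed-and-extend search.

    ``k`` is the exact seed size; ``max_chain_gap`` bounds genomic gaps a
    chain may bridge (intron-sized); ``band`` is the alignment band beyond
    the length difference of each segment; ``g_intron`` is the smallest
    genomic-side gap treated as an intron rather than an indel.
    """

    k: int = 12
    min_identity: float = 0.70
    min_coverage: float = 0.50
    max_chain_gap: int = 30_000
    seg_band: int = 20
    band: int = 48
    g_intron: int = 50
    min_seed_count: int = 2
    pad: int = 24
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class HomologyHit:
    """A genomic match of the query cDNA.

    ``segments`` are the aligned target blocks (1-based inclusive, forward
    strand); for a spliced (parent-like) hit there is one per exon, and
    their concatenation is the locus's implied transcript sequence.
    """

    query_id: str
    query_span: Tuple[int, int]  # 1-based inclusive on the cDNA
    target: GenomicInterval
    aligned_columns: int
    matches: int
    identity: float
    intron_gap_blocks: int
    coverage: float
    score: int
    segments: Tuple[Tuple[int, int], ...] = ()


@dataclass
class LocusClassification:
    hit: HomologyHit
    locus_class: str  # parent | pseudogene | paralog
    intronless: bool
    orf_intact: bool
    orf_fraction: float
    name: Optional[str] = None


def _kmer_index(seq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _cluster_seeds(seeds, params: HomologySearchParams):
    """Group (diag, t, q) seeds into same-diagonal segments."""
    seeds = sorted(seeds)
    segments = []
    cur = []
    for d, t, q in seeds:
        if cur and (d - cur[-1][0] > params.seg_band or t - cur[-1][1] > 1000):
            segments.append(cur)
            cur = []
        cur.append((d, t, q))
    if cur:
        segments.append(cur)
    out = []
    for seg in segments:
        if len(seg) < params.min_seed_count:
            continue
        ts = [s[1] for s in seg]
        qs = [s[2] for s in seg]
        out.append(
            {
                "q_start": min(qs),
                "q_end": max(qs) + params.k,
                "t_start": min(ts),
                "t_end": max(ts) + params.k,
                "n_seeds": len(seg),
            }
        )
    return out


def _chain_segments(segments, params: HomologySearchParams):
    """Colinear chaining of segments; returns chains as lists of segments."""
    segs = sorted(segments, key=lambda s: (s["t_start"], s["q_start"]))
    n = len(segs)
    best = [s["n_seeds"] for s in segs]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = segs[j], segs[i]
            if (
                b["t_start"] >= a["t_end"] - params.seg_band
                and b["q_start"] >= a["q_end"] - params.seg_band
                and b["t_start"] - a["t_end"] <= params.max_chain_gap
            ):
                cand = best[j] + segs[i]["n_seeds"]
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    used = [False] * n
    chains = []
    for i in sorted(range(n), key=lambda i: -best[i]):
        if used[i]:
            continue
        chain = []
        j = i
        ok = True
        while j != -1:
            if used[j]:
                ok = False
                break
            chain.append(j)
            j = prev[j]
        if not ok:
            continue
        for j in chain:
            used[j] = True
        chains.append([segs[j] for j in reversed(chain)])
    return chains


_MIN_FILL = 25  # unseeded query stretches at least this long get their own block
_FILL_MIN_IDENTITY = 0.70  # random-sequence glocal alignments top out near 0.65


def _refine_junction(qseq: str, tseq: str, left, right, w: int):
    """Gapless split search over an intron-like joint.

    Seeds stop short of exon edges, so the query bases between two chained
    segments must be divided between the upstream exon's end and the
    downstream exon's start. For every split point the matches of the
    prefix on the left diagonal plus the suffix on the right diagonal are
    counted; the best split (ties: leftmost) fixes the exact boundary.
    """
    m, n = len(qseq), len(tseq)
    jq0 = max(0, left["q_end"] - w, left["q_end"] - left["t_end"])
    jq1 = min(m, right["q_start"] + w, right["q_start"] + (n - right["t_start"]))
    if jq1 <= jq0 or jq0 > left["q_end"] or jq1 < right["q_start"]:
        q_split = right["q_start"]
        return q_split, left["t_end"] + (q_split - left["q_end"]), right["t_start"]
    tL0 = left["t_end"] - (left["q_end"] - jq0)
    tR1 = right["t_start"] + (jq1 - right["q_start"])
    Q = qseq[jq0:jq1]
    L = len(Q)
    left_t = tseq[tL0 : tL0 + L]
    right_t = tseq[tR1 - L : tR1]
    pref = [0]
    for i, ch in enumerate(Q):
        pref.append(pref[-1] + (1 if i < len(left_t) and ch == left_t[i] else 0))
    suf = [0] * (L + 1)
    for i in range(L - 1, -1, -1):
        suf[i] = suf[i + 1] + (1 if Q[i] == right_t[i] else 0)
    best_k = max(range(L + 1), key=lambda k: (pref[k] + suf[k], -k))
    return jq0 + best_k, tL0 + best_k, tR1 - (L - best_k)


def _align_chain(chain, qseq: str, tseq: str, params: HomologySearchParams):
    """Alignment of a chained locus, block by block.

    Seeded segments are aligned in banded windows with exact, refined
    boundaries at intron-like joints (so the concatenated target segments
    form a frame-faithful implied transcript). Unseeded query stretches of
    at least ``_MIN_FILL`` bp — missed exons, diverged or absent ends — are
    aligned separately into the intervening target window and accepted only
    above ``_FILL_MIN_IDENTITY``: a truncated copy's missing tail shows up
    as reduced coverage, not dragged-down identity.
    """
    m, n = len(qseq), len(tseq)
    w = 2 * params.pad
    joints = []
    for left, right in zip(chain, chain[1:]):
        q_gap = right["q_start"] - left["q_end"]
        t_gap = right["t_start"] - left["t_end"]
        if t_gap - q_gap >= params.g_intron and q_gap <= 90:
            w_eff = max(w, q_gap + params.pad)
            joints.append(("split",) + _refine_junction(qseq, tseq, left, right, w_eff))
        elif q_gap >= _MIN_FILL:
            joints.append(("fill",))
        else:
            joints.append(("absorb",))
    blocks = []
    first = chain[0]
    if first["q_start"] >= _MIN_FILL:
        blocks.append(
            {
                "kind": "fill",
                "q0": 0,
                "q1": first["q_start"],
                "t0": max(0, first["t_start"] - first["q_start"] - 4 * params.pad),
                "t1": first["t_start"] + params.pad,
            }
        )
        q0, t0 = first["q_start"], first["t_start"] - params.pad
    else:
        q0, t0 = 0, first["t_start"] - first["q_start"] - params.pad
    for i, seg in enumerate(chain):
        if i < len(joints):
            joint, right = joints[i], chain[i + 1]
            if joint[0] == "fill":
                q1, t1 = seg["q_end"], seg["t_end"] + params.pad
            elif joint[0] == "split":
                q1, t1 = joint[1], joint[2]
            else:
                q1 = right["q_start"]
                t1 = seg["t_end"] + (q1 - seg["q_end"]) + params.pad
        else:
            q1 = m if m - seg["q_end"] < _MIN_FILL else seg["q_end"]
            t1 = seg["t_end"] + (q1 - seg["q_end"]) + params.pad
        blocks.append(
            {"kind": "seg", "q0": q0, "q1": q1, "t0": max(0, t0), "t1": min(n, t1)}
        )
        if i < len(joints):
            joint, right = joints[i], chain[i + 1]
            if joint[0] == "fill":
                blocks.append(
                    {
                        "kind": "fill",
                        "q0": seg["q_end"],
                        "q1": right["q_start"],
                        "t0": max(0, seg["t_end"] - params.pad),
                        "t1": right["t_start"] + params.pad,
                    }
                )
                q0, t0 = right["q_start"], right["t_start"] - params.pad
            elif joint[0] == "split":
                q0, t0 = joint[1], joint[3]
            else:
                q0, t0 = right["q_start"], right["t_start"] - params.pad
    last = chain[-1]
    if m - last["q_end"] >= _MIN_FILL:
        blocks.append(
            {
                "kind": "fill",
                "q0": last["q_end"],
                "q1": m,
                "t0": max(0, last["t_end"] - params.pad),
                "t1": min(n, last["t_end"] + (m - last["q_end"]) + 4 * params.pad),
            }
        )
    pieces = []
    for b in blocks:
        q0, q1 = b["q0"], b["q1"]
        t0, t1 = b["t0"], min(n, b["t1"])
        if pieces:
            t0 = max(t0, pieces[-1]["t_end"])
        if q1 <= q0 or t1 <= t0:
            continue
        aln = affine_align(
            qseq[q0:q1],
            tseq[t0:t1],
            match=params.match,
            mismatch=params.mismatch,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
            band=params.band if b["kind"] == "seg" else None,
            free_target_ends=True,
            trim_query_end_gaps=True,
        )
        if aln.columns == 0:
            continue
        if b["kind"] == "fill" and aln.identity < _FILL_MIN_IDENTITY:
            continue
        pieces.append(
            {
                "q_start": q0 + aln.query_start,
                "q_end": q0 + aln.query_end,
                "t_start": t0 + aln.target_start,
                "t_end": t0 + aln.target_end,
                "matches": aln.matches,
                "columns": aln.columns,
                "score": aln.score,
            }
        )
    if not pieces:
        return None
    intron_blocks = 0
    for a, b in zip(pieces, pieces[1:]):
        t_gap = b["t_start"] - a["t_end"]
        q_gap = b["q_start"] - a["q_end"]
        if t_gap - q_gap >= params.g_intron:
            intron_blocks += 1
    return {
        "q_start": pieces[0]["q_start"],
        "q_end": pieces[-1]["q_end"],
        "t_start": pieces[0]["t_start"],
        "t_end": pieces[-1]["t_end"],
        "matches": sum(p["matches"] for p in pieces),
        "columns": sum(p["columns"] for p in pieces),
        "score": sum(p["score"] for p in pieces),
        "aligned_q": sum(p["q_end"] - p["q_start"] for p in pieces),
        "intron_blocks": intron_blocks,
        "segments": tuple((p["t_start"] + 1, p["t_end"]) for p in pieces),
    }


def find_homologous_loci(
    cdna: SequenceRecord,
    genome: Sequence[SequenceRecord],
    params: Optional[HomologySearchParams] = None,
) -> List[HomologyHit]:
    """Find loci homologous to *cdna* in *genome* on both strands.

    Hits pass ``min_identity`` and ``min_coverage`` filters; overlapping
    hits on one locus are merged keeping the best raw score (ties: leftmost
    start). Results are sorted by descending identity.
    """
    params = params or HomologySearchParams()
    m = len(cdna.seq)
    if params.k > m:
        raise ValueError(f"seed size k={params.k} exceeds cDNA length {m}")
    if not genome:
        raise ValueError("empty genome")
    raw_hits: List[HomologyHit] = []
    for rec in genome:
        for strand in ("+", "-"):
            qseq = cdna.seq if strand == "+" else reverse_complement(cdna.seq)
            index = _kmer_index(qseq, params.k)
            seeds = []
            tseq = rec.seq
            for t in range(len(tseq) - params.k + 1):
                kmer = tseq[t : t + params.k]
                for q in index.get(kmer, ()):
                    seeds.append((t - q, t, q))
            if not seeds:
                continue
            segments = _cluster_seeds(seeds, params)
            if not segments:
                continue
            for chain in _chain_segments(segments, params):
                stats = _align_chain(chain, qseq, tseq, params)
                if stats is None or stats["columns"] == 0:
                    continue
                if strand == "+":
                    q_span = (stats["q_start"] + 1, stats["q_end"])
                else:
                    q_span = (m - stats["q_end"] + 1, m - stats["q_start"])
                raw_hits.append(
                    HomologyHit(
                        query_id=cdna.id,
                        query_span=q_span,
                        target=GenomicInterval.from_slice(
                            rec.id, stats["t_start"], stats["t_end"], strand
                        ),
                        aligned_columns=stats["columns"],
                        matches=stats["matches"],
                        identity=stats["matches"] / stats["columns"],
                        intron_gap_blocks=stats["intron_blocks"],
                        coverage=stats["aligned_q"] / m,
                        score=stats["score"],
                        segments=stats["segments"],
                    )
                )
    # merge overlapping hits per locus, best score wins; ties -> leftmost
    raw_hits.sort(key=lambda h: (-h.score, h.target.chrom, h.target.start))
    kept: List[HomologyHit] = []
    for hit in raw_hits:
        if any(
            k.target.chrom == hit.target.chrom
            and k.target.start <= hit.target.end
            and hit.target.start <= k.target.end
            for k in kept
        ):
            continue
        kept.append(hit)
    kept = [
        h
        for h in kept
        if h.identity >= params.min_identity and h.coverage >= params.min_coverage
    ]
    kept.sort(key=lambda h: (-h.identity, h.target.chrom, h.target.start))
    return kept


_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def _spliced_orf_fraction(
    implied: str,
    boundaries: List[int],
    cdna_seq: str,
    cds: Tuple[int, int],
    boundary_slop: int = 6,
) -> float:
    """ORF integrity of an implied (spliced) transcript, read through an
    alignment to the parent cDNA.

    Junction reconstruction can slide a few bases, so codons within
    *boundary_slop* of a segment boundary never count as disruptions; a
    stop read from a cleanly aligned interior codon, or an unaligned
    stretch, breaks the reading frame. Returns the longest clean codon run
    as a fraction of the parent CDS length.
    """
    # stiff gap costs: gaps should appear only at true indels (missing
    # exons, junction slides), never as mismatch-avoiding detours that
    # would scramble the reading frame
    aln = affine_align(implied, cdna_seq, band=96, gap_open=-16, gap_extend=-8)
    n = len(cdna_seq)
    imp_base: List[Optional[str]] = [None] * (n + 1)
    imp_pos: List[int] = [0] * (n + 1)
    qi, tj = aln.query_start, aln.target_start
    for op in aln.ops:
        if op == "M":
            imp_base[tj + 1] = implied[qi]
            imp_pos[tj + 1] = qi
            qi += 1
            tj += 1
        elif op == "I":
            tj += 1
        else:
            qi += 1
    cds_start, cds_end = cds
    cds_len = cds_end - cds_start + 1
    starts = list(range(cds_start, cds_end - 1, 3))
    readable = []
    for c0 in starts:
        triplet = [imp_base[p] for p in (c0, c0 + 1, c0 + 2)]
        readable.append(not any(b is None for b in triplet))
    # unreadable stretch lengths (a missing exon breaks the frame; a short
    # reconstruction hole does not)
    stretch = [0] * len(starts)
    i = 0
    while i < len(starts):
        if not readable[i]:
            j = i
            while j < len(starts) and not readable[j]:
                j += 1
            for k in range(i, j):
                stretch[k] = j - i
            i = j
        else:
            i += 1
    run = best = 0
    for idx, c0 in enumerate(starts):
        if not readable[idx]:
            if stretch[idx] > 4:
                best = max(best, run)
                run = 0
            continue  # short hole: neutral
        triplet = "".join(imp_base[p] for p in (c0, c0 + 1, c0 + 2))
        if triplet in _STOP_CODONS:
            near_boundary = any(
                abs(imp_pos[p] - b) <= boundary_slop
                for p in (c0, c0 + 1, c0 + 2)
                for b in boundaries
            )
            if near_boundary:
                continue  # junction slide artifact: neutral
            best = max(best, run)
            run = 0
            continue
        run += 1
    best = max(best, run)
    return best * 3 / cds_len if cds_len else 0.0


def _longest_orf(seq: str) -> int:
    """Longest ATG..stop open reading frame (nt, incl. stop) on this strand."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in stops:
                best = max(best, i + 3 - start)
                start = None
    return best


def classify_locus(
    hit: HomologyHit,
    parent_model: GeneModel,
    parent_cds: Tuple[int, int],
    genome: Sequence[SequenceRecord],
    cdna: Optional[SequenceRecord] = None,
    g_intron: int = 50,
    orf_frac: float = 0.9,
    name: Optional[str] = None,
) -> LocusClassification:
    """Classify a hit as parent, pseudogene, or paralog.

    *parent_cds* is the CDS interval (1-based inclusive) on the parent
    cDNA. ``intronless`` means the chained alignment shows no genomic-side
    gap of at least *g_intron* bp. For an intronless copy ``orf_intact``
    asks whether the locus sequence itself carries an open reading frame of
    at least ``orf_frac`` of the parent CDS; for an intron-containing hit
    (when *cdna* is supplied) the implied spliced transcript is read
    codon-by-codon against the parent CDS instead, because junction
    reconstruction is not base-exact.
    """
    by_id = {r.id: r for r in genome}
    chrom_seq = by_id[hit.target.chrom].seq
    cds_len = parent_cds[1] - parent_cds[0] + 1
    intronless = hit.intron_gap_blocks == 0
    if not intronless and hit.segments and cdna is not None:
        segs = list(hit.segments)
        parts = [chrom_seq[s - 1 : e] for s, e in segs]
        implied = "".join(parts)
        lengths = [len(p) for p in parts]
        if hit.target.strand == "-":
            implied = reverse_complement(implied)
            lengths = lengths[::-1]
        boundaries, acc = [], 0
        for L in lengths[:-1]:
            acc += L
            boundaries.append(acc)
        orf_fraction = _spliced_orf_fraction(implied, boundaries, cdna.seq, parent_cds)
    else:
        if hit.segments:
            locus_seq = "".join(chrom_seq[s - 1 : e] for s, e in hit.segments)
        else:
            locus_seq = chrom_seq[hit.target.to_slice()]
        if hit.target.strand == "-":
            locus_seq = reverse_complement(locus_seq)
        orf_fraction = _longest_orf(locus_seq) / cds_len if cds_len else 0.0
    orf_intact = orf_fraction >= orf_frac
    if hit.target.chrom != parent_model.chrom:
        is_parent = False
        logger.debug("hit on %s, parent on %s", hit.target.chrom, parent_model.chrom)
    else:
        is_parent = hit.target.overlaps(parent_model.extent)
    if is_parent:
        locus_class = "parent"
    elif intronless or not orf_intact:
        locus_class = "pseudogene"
    else:
        locus_class = "paralog"
    return LocusClassification(
        hit=hit,
        locus_class=locus_class,
        intronless=intronless,
        orf_intact=orf_intact,
        orf_fraction=orf_fraction,
        name=name,
    )


def catalog_report(classifications: Sequence[LocusClassification]) -> pd.DataFrame:
    """Tabulate classified loci: parent first, then descending identity."""
    if not classifications:
        raise ValueError("no classifications to report")
    rows = []
    ordered = sorted(
        classifications,
        key=lambda c: (c.locus_class != "parent", -c.hit.identity, c.hit.target.chrom),
    )
    for i, c in enumerate(ordered):
        rows.append(
            {
                "name": c.name or f"locus_{c.hit.target.chrom}_{c.hit.target.start}",
                "coordinate": str(c.hit.target),
                "span_bp": c.hit.target.span,
                "identity_pct": round(100.0 * c.hit.identity, 2),
                "class": c.locus_class,
            }
        )
    return pd.DataFrame(rows, columns=["name", "coordinate", "span_bp", "identity_pct", "class"])
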