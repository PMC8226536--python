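"""Discriminating-site detection and PCR assay design.

Three assay classes are supported, mirroring how one separates a parent
gene's transcripts from processed-pseudogene transcripts:

* **allele-specific** primers whose 3'-terminal base sits on a position
  unique to the design template among its homologs (extension from a 3'
  mismatch is inefficient, so off-targets amplify weakly at best);
* **splice-junction** assays in which one primer straddles an exon-exon
  junction of the spliced cDNA (excludes genomic DNA);
* **primary-transcript** assays placed across an exon-intron boundary or
  wholly inside an intron — intronless pseudogene copies carry no binding
  site at all, making pre-mRNA a clean surrogate for parent transcription.

Homolog columns are obtained by star alignment: each paralog is aligned
pairwise to the target and projected onto target coordinates (insertions
relative to the target are dropped). A full multiple alignment is not used;
discriminating sites are defined relative to the target, and the star
projection is deterministic regardless of input order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .align import affine_align
from .seqio import GeneModel, SequenceRecord, reverse_complement

PRIMER_BASES = frozenset("ACGT")


class DesignError(ValueError):
    """No assay satisfying the constraints exists."""


# ---------------------------------------------------------------------------
# melting temperature

# SantaLucia (1998) unified nearest-neighbor parameters.
# dH in kcal/mol, dS in cal/(mol*K), 5'->3' top-strand dinucleotides.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R = 1.987  # cal/(mol*K)


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, na_mM: float = 50.0, primer_nM: float = 500.0) -> float:
    """Primer melting temperature in degrees C.

    Nearest-neighbor duplex thermodynamics (unified parameter set) with the
    entropic salt correction 0.368*(N-1)*ln[Na+] and total-strand
    concentration term R*ln(C/4); short oligos (< 14 nt) fall back to the
    Wallace rule 2(A+T) + 4(G+C).
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("primer too short for a meaningful Tm (< 8 nt)")
    bad = set(seq) - PRIMER_BASES
    if bad:
        raise ValueError(f"primer contains non-ACGT characters: {sorted(bad)}")
    if len(seq) < 14:
        at = seq.count("A") + seq.count("T")
        gc = len(seq) - at
        return 2.0 * at + 4.0 * gc
    dh, ds = 0.0, 0.0
    for a, b in ((seq[0], _INIT_GC if seq[0] in "GC" else _INIT_AT),
                 (seq[-1], _INIT_GC if seq[-1] in "GC" else _INIT_AT)):
        dh += b[0]
        ds += b[1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    c = primer_nM * 1e-9
    return (1000.0 * dh) / (ds + _R * math.log(c / 4.0)) - 273.15


# ---------------------------------------------------------------------------
# star alignment and discriminating sites


@dataclass
class ColumnTable:
    """Per-target-position bases of each paralog ('-' = gap)."""

    target_id: str
    target_seq: str
    columns: pd.DataFrame  # index: 1-based target position; columns: paralog ids

    @property
    def paralog_ids(self) -> List[str]:
        return list(self.columns.columns)


@dataclass(frozen=True)
class DiscriminatingSite:
    """A target position at which at least one paralog differs."""

    position: int  # 1-based on the target
    target_base: str
    paralog_bases: Tuple[Tuple[str, str], ...]
    distinguishing: frozenset

    def __post_init__(self):
        if not self.distinguishing:
            raise ValueError("distinguishing set must be non-empty")


def align_to_target(
    target: SequenceRecord,
    paralogs: Sequence[SequenceRecord],
    min_coverage: float = 0.5,
    band: int = 96,
) -> ColumnTable:
    """Star-align paralogs to *target*, projected onto target coordinates.

    Paralogs whose alignable coverage of the target is below *min_coverage*
    are excluded with a warning.
    """
    if not paralogs:
        raise ValueError("at least one paralog required")
    L = len(target.seq)
    data: Dict[str, np.ndarray] = {}
    for p in paralogs:
        # stiff gap costs: the projection wants colinear columns, with gaps
        # reserved for real indels rather than mismatch-avoiding detours
        aln = affine_align(p.seq, target.seq, band=band, gap_open=-12, gap_extend=-6)
        col = np.full(L, "-", dtype="<U1")
        qi, tj = aln.query_start, aln.target_start
        matched = 0
        for op in aln.ops:
            if op == "M":
                col[tj] = p.seq[qi]
                if p.seq[qi] == target.seq[tj]:
                    matched += 1
                qi += 1
                tj += 1
            elif op == "I":
                tj += 1
            else:
                qi += 1
        # alignable coverage = identical columns over the target length, so
        # unrelated sequence (forced through a global alignment) is excluded
        if matched / L < min_coverage:
            warnings.warn(
                f"paralog '{p.id}' matches only {matched / L:.0%} of the target; excluded"
            )
            continue
        data[p.id] = col
    if not data:
        raise DesignError("no paralog passed the coverage filter")
    frame = pd.DataFrame(data, index=np.arange(1, L + 1))
    return ColumnTable(target.id, target.seq, frame)


def find_discriminating_sites(
    table: ColumnTable,
    mode: str = "unique_to_target",
    paralog_id: Optional[str] = None,
) -> List[DiscriminatingSite]:
    """Positions that uniquely identify the target (or one paralog).

    ``unique_to_target``: the target base differs from every paralog.
    ``unique_to_paralog``: *paralog_id*'s base differs from the target and
    from every other paralog (for pseudogene-specific primers).
    """
    ids = table.paralog_ids
    if mode == "unique_to_paralog":
        if paralog_id not in ids:
            raise KeyError(f"unknown paralog id {paralog_id!r}")
    elif mode != "unique_to_target":
        raise ValueError(f"unknown mode {mode!r}")
    sites = []
    cols = table.columns
    for pos in cols.index:
        tbase = table.target_seq[pos - 1]
        row = cols.loc[pos]
        if mode == "unique_to_target":
            ok = all(row[p] != tbase for p in ids)
        else:
            pbase = row[paralog_id]
            ok = pbase != tbase and all(
                row[p] != pbase for p in ids if p != paralog_id
            )
        if ok:
            differing = frozenset(p for p in ids if row[p] != tbase)
            sites.append(
                DiscriminatingSite(
                    position=int(pos),
                    target_base=tbase,
                    paralog_bases=tuple((p, row[p]) for p in ids),
                    distinguishing=differing,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# primers and assays


@dataclass(frozen=True)
class Primer:
    """A synthesized oligo, 5'->3', with its footprint on the design template.

    ``start``/``end`` are 1-based inclusive template coordinates of the
    footprint; for a ``-`` primer the 3' end is at ``start``.
    ``anchored_offsets`` are 3'-offsets (0 = terminal base) of covered
    discriminating sites.
    """

    name: str
    seq: str
    strand: str
    start: int
    end: int
    tm: float
    anchored_offsets: Tuple[int, ...] = ()

    def __post_init__(self):
        bad = set(self.seq) - PRIMER_BASES
        if bad:
            raise ValueError(f"primer {self.name}: non-ACGT characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def three_prime_pos(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class PrimerConstraints:
    """Standard qPCR design envelope (lengths, Tm, GC, product size)."""

    min_len: int = 18
    max_len: int = 25
    tm_target: float = 60.0
    tm_min: float = 57.0
    tm_max: float = 63.0
    gc_min: float = 0.35
    gc_max: float = 0.65
    anchor_window: int = 5
    require_second_site: bool = False
    min_overhang: int = 4
    product_min: int = 70
    product_max: int = 250


@dataclass
class AssayDesign:
    """A designed primer pair (optionally with an internal probe)."""

    id: str
    assay_class: str  # allele_specific | splice_junction | exon_intron | intra_intron
    forward: Primer
    reverse: Primer
    amplicon_length: int
    template_id: str = ""
    probe: Optional[str] = None

    def __post_init__(self):
        if {self.forward.strand, self.reverse.strand} != {"+", "-"}:
            raise ValueError("assay primers must be on opposite strands")
        expected = self.reverse.end - self.forward.start + 1
        if self.amplicon_length != expected:
            raise ValueError(
                f"amplicon length {self.amplicon_length} != primer outer-end distance {expected}"
            )


def _template_seq(template: Union[str, SequenceRecord]) -> Tuple[str, str]:
    if isinstance(template, SequenceRecord):
        return template.seq, template.id
    return template, "template"


def enumerate_allele_specific_primers(
    template: Union[str, SequenceRecord],
    sites: Sequence[Union[int, DiscriminatingSite]],
    constraints: Optional[PrimerConstraints] = None,
) -> List[Primer]:
    """All constraint-satisfying primers with a 3'-terminal discriminating base.

    For every site and both strands, every length in the allowed range is
    considered; candidates are filtered by Tm and GC windows (and optionally
    a second site within ``anchor_window`` of the 3' end) and sorted by
    (number of 3'-anchored sites desc, |Tm - target| asc, position asc).
    """
    c = constraints or PrimerConstraints()
    seq, tid = _template_seq(template)
    positions = sorted(
        {s.position if isinstance(s, DiscriminatingSite) else int(s) for s in sites}
    )
    if not positions:
        return []
    pos_set = set(positions)
    out = []
    n = len(seq)
    for p in positions:
        for length in range(c.min_len, c.max_len + 1):
            # forward: footprint [p-length+1, p], 3' end at p
            a = p - length + 1
            if a >= 1:
                s = seq[a - 1 : p]
                cand = _make_candidate(s, "+", a, p, pos_set, c, tid)
                if cand:
                    out.append(cand)
            # reverse: footprint [p, p+length-1], 3' end at p
            b = p + length - 1
            if b <= n:
                s = reverse_complement(seq[p - 1 : b])
                cand = _make_candidate(s, "-", p, b, pos_set, c, tid)
                if cand:
                    out.append(cand)
    out.sort(
        key=lambda pr: (
            -sum(1 for o in pr.anchored_offsets if o < c.anchor_window),
            abs(pr.tm - c.tm_target),
            pr.three_prime_pos,
            pr.strand,
        )
    )
    return out


def _make_candidate(s, strand, start, end, pos_set, c, tid):
    if set(s) - PRIMER_BASES:
        return None
    gc = gc_fraction(s)
    if not (c.gc_min <= gc <= c.gc_max):
        return None
    tm = melting_temperature(s)
    if not (c.tm_min <= tm <= c.tm_max):
        return None
    covered = range(start, end + 1)
    if strand == "+":
        offsets = tuple(sorted(end - q for q in pos_set if q in covered))
    else:
        offsets = tuple(sorted(q - start for q in pos_set if q in covered))
    if c.require_second_site and sum(1 for o in offsets if o < c.anchor_window) < 2:
        return None
    name = f"{tid}_as_{strand}{start}_{len(s)}"
    return Primer(name, s, strand, start, end, tm, offsets)


def _min_mismatches(primer: str, template: str) -> int:
    """Fewest mismatches of *primer* against any window of *template* (both strands)."""
    best = len(primer)
    tcode = np.frombuffer(template.encode(), dtype=np.uint8)
    for probe in (primer, reverse_complement(primer)):
        pc = np.frombuffer(probe.encode(), dtype=np.uint8)
        if len(pc) > len(tcode):
            continue
        win = np.lib.stride_tricks.sliding_window_view(tcode, len(pc))
        mm = (win != pc).sum(axis=1)
        best = min(best, int(mm.min()))
    return best


def _plain_primer(seq, strand, start, end, name):
    return Primer(name, seq, strand, start, end, melting_temperature(seq))


def design_junction_assay(
    model: GeneModel,
    cdna: Union[str, SequenceRecord],
    exon_pair: Tuple[int, int],
    constraints: Optional[PrimerConstraints] = None,
    homologs: Optional[Sequence[SequenceRecord]] = None,
    assay_id: Optional[str] = None,
) -> AssayDesign:
    """Design a spliced-cDNA assay whose forward primer straddles a junction.

    *exon_pair* ``(i, i+1)`` selects the junction. When *homologs* are
    given, candidates binding all of them with the fewest worst-case
    mismatches are preferred — the behaviour of pan-transcript assays that
    sit in conserved exonic sequence and therefore co-amplify homologous
    templates.
    """
    c = constraints or PrimerConstraints()
    i, j = exon_pair
    if j != i + 1:
        raise ValueError("exon pair must be adjacent, (i, i+1)")
    if j > len(model.exons) or i < 1:
        raise DesignError(f"gene has {len(model.exons)} exons; no junction {i}/{j}")
    seq, tid = _template_seq(cdna)
    n = len(seq)
    J = model.cdna_junctions()[i - 1]
    ov = c.min_overhang
    hseqs = [h.seq for h in homologs] if homologs else []

    fwd_cands = []
    for length in range(c.min_len, c.max_len + 1):
        for a in range(max(1, J + ov - length + 1), J - ov + 2):
            end = a + length - 1
            if end > n or end < J + ov:
                continue
            s = seq[a - 1 : end]
            if set(s) - PRIMER_BASES:
                continue
            tm = melting_temperature(s)
            pen = max((_min_mismatches(s, h) for h in hseqs), default=0)
            fwd_cands.append((pen, abs(tm - c.tm_target), a, _plain_primer(s, "+", a, end, "F")))
    if not fwd_cands:
        raise DesignError("no feasible design: junction too close to transcript end")
    fwd_cands.sort(key=lambda x: x[:3])

    rev_cands = []
    for length in range(c.min_len, c.max_len + 1):
        for b in range(J + 1, n - length + 2):
            end = b + length - 1
            s = reverse_complement(seq[b - 1 : end])
            if set(s) - PRIMER_BASES:
                continue
            tm = melting_temperature(s)
            pen = max((_min_mismatches(s, h) for h in hseqs), default=0)
            rev_cands.append((pen, abs(tm - c.tm_target), b, end, s))
    for f_pen, f_dev, a, fwd in fwd_cands[:10]:
        feasible = [
            (pen, dev, b, end, s)
            for pen, dev, b, end, s in rev_cands
            if b > fwd.end and c.product_min <= end - a + 1 <= c.product_max
        ]
        if not feasible:
            continue
        pen, dev, b, end, s = min(feasible, key=lambda x: (x[0], x[1], x[2]))
        rev = _plain_primer(s, "-", b, end, "R")
        aid = assay_id or f"{tid}_ex{i}_ex{j}"
        fwd = Primer(f"{aid}_F", fwd.seq, "+", fwd.start, fwd.end, fwd.tm)
        rev = Primer(f"{aid}_R", rev.seq, "-", rev.start, rev.end, rev.tm)
        return AssayDesign(aid, "splice_junction", fwd, rev, end - a + 1, tid)
    raise DesignError("no feasible design: no mate within the product window")


def design_primary_transcript_assay(
    model: GeneModel,
    chrom_seq: str,
    mode: str,
    intron_index: int,
    constraints: Optional[PrimerConstraints] = None,
    assay_id: Optional[str] = None,
) -> AssayDesign:
    """Design an intron-dependent assay on the unspliced transcript.

    ``exon_intron``: forward primer inside exon *i*, reverse inside intron
    *i*, amplicon crossing the boundary. ``intra_intron``: both primers
    inside intron *i*. Intronless templates carry no binding site for
    either class. Coordinates are genomic (model must be a + strand gene).
    """
    c = constraints or PrimerConstraints()
    introns = model.introns
    if not introns:
        raise DesignError("no introns: primary-transcript design impossible")
    if not (1 <= intron_index <= len(introns)):
        raise DesignError(f"gene has {len(introns)} introns; no intron {intron_index}")
    intron = introns[intron_index - 1]
    if mode == "exon_intron":
        exon = model.exons[intron_index - 1]
        f_lo, f_hi = exon.start, exon.end
        r_lo, r_hi = intron.start, intron.end
    elif mode == "intra_intron":
        if intron.span < c.product_min:
            raise DesignError(
                f"intron {intron_index} ({intron.span} bp) shorter than minimum product {c.product_min}"
            )
        f_lo, f_hi = intron.start, intron.end
        r_lo, r_hi = intron.start, intron.end
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fwd_cands = []
    for length in range(c.min_len, c.max_len + 1):
        lo = max(f_lo, f_hi - c.product_max + 1)
        for a in range(lo, f_hi - length + 2):
            end = a + length - 1
            if end > f_hi:
                continue
            s = chrom_seq[a - 1 : end]
            if set(s) - PRIMER_BASES:
                continue
            tm = melting_temperature(s)
            fwd_cands.append((abs(tm - c.tm_target), a, _plain_primer(s, "+", a, end, "F")))
    fwd_cands.sort(key=lambda x: (x[0], x[1]))
    for dev, a, fwd in fwd_cands[:20]:
        best = None
        for length in range(c.min_len, c.max_len + 1):
            for b in range(max(r_lo, fwd.end + 1), r_hi - length + 2):
                end = b + length - 1
                if end > r_hi:
                    continue
                product = end - a + 1
                if not (c.product_min <= product <= c.product_max):
                    continue
                s = reverse_complement(chrom_seq[b - 1 : end])
                if set(s) - PRIMER_BASES:
                    continue
                tm = melting_temperature(s)
                key = (abs(tm - c.tm_target), product, b)
                if best is None or key < best[0]:
                    best = (key, b, end, s, tm)
        if best is None:
            continue
        _, b, end, s, tm = best
        aid = assay_id or f"{model.gene_id}_{mode}_{intron_index}"
        fwd = Primer(f"{aid}_F", fwd.seq, "+", fwd.start, fwd.end, fwd.tm)
        rev = Primer(f"{aid}_R", s, "-", b, end, tm)
        cls = "exon_intron" if mode == "exon_intron" else "intra_intron"
        return AssayDesign(aid, cls, fwd, rev, end - fwd.start + 1, model.gene_id)
    raise DesignError("no feasible design within the product window")


def pair_allele_specific_assay(
    template: SequenceRecord,
    sites: Sequence[DiscriminatingSite],
    constraints: Optional[PrimerConstraints] = None,
    assay_id: Optional[str] = None,
) -> AssayDesign:
    """Build a primer *pair* from allele-specific candidates on one template.

    Prefers both primers 3'-anchored on discriminating sites; if no anchored
    mate fits the product window, the reverse primer falls back to a plain
    oligo chosen by Tm. Raises :class:`DesignError` when no forward anchored
    primer exists at all.
    """
    c = constraints or PrimerConstraints()
    cands = enumerate_allele_specific_primers(template, sites, c)
    fwds = [p for p in cands if p.strand == "+"]
    revs = [p for p in cands if p.strand == "-"]
    aid = assay_id or f"{template.id}_specific"
    for fwd in fwds[:20]:
        mates = [
            r
            for r in revs
            if r.start > fwd.end and c.product_min <= r.end - fwd.start + 1 <= c.product_max
        ]
        if mates:
            rev = mates[0]
            return AssayDesign(
                aid, "allele_specific",
                Primer(f"{aid}_F", fwd.seq, "+", fwd.start, fwd.end, fwd.tm, fwd.anchored_offsets),
                Primer(f"{aid}_R", rev.seq, "-", rev.start, rev.end, rev.tm, rev.anchored_offsets),
                rev.end - fwd.start + 1, template.id,
            )
    # plain reverse fallback
    n = len(template.seq)
    for fwd in fwds[:20]:
        best = None
        for length in range(c.min_len, c.max_len + 1):
            for b in range(fwd.end + 1, n - length + 2):
                end = b + length - 1
                product = end - fwd.start + 1
                if not (c.product_min <= product <= c.product_max):
                    continue
                s = reverse_complement(template.seq[b - 1 : end])
                if set(s) - PRIMER_BASES:
                    continue
                gc = gc_fraction(s)
                if not (c.gc_min <= gc <= c.gc_max):
                    continue
                tm = melting_temperature(s)
                key = (abs(tm - c.tm_target), b)
                if best is None or key < best[0]:
                    best = (key, b, end, s, tm)
        if best:
            _, b, end, s, tm = best
            return AssayDesign(
                aid, "allele_specific",
                Primer(f"{aid}_F", fwd.seq, "+", fwd.start, fwd.end, fwd.tm, fwd.anchored_offsets),
                Primer(f"{aid}_R", s, "-", b, end, tm),
                end - fwd.start + 1, template.id,
            )
    raise DesignError(f"no allele-specific pair for {template.id}")
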