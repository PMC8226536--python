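"""In-silico PCR: 3'-weighted primer binding, amplification calls, poly-T sizing.

Binding uses a position-weight mismatch model rather than thermodynamics: a
mismatch at the 3'-terminal base nearly abolishes extension (weight 0.9), a
mismatch in the rest of the 3' anchor is strongly penalized (0.6 at offsets
1-2, 0.3 at 3-4), and body mismatches cost little (0.1). A site's score is
the product of ``1 - w`` over its mismatched positions, so a single
3'-terminal mismatch leaves a residual 0.1 — the "leaky" behaviour of
allele-specific primers. Indels and degenerate bases are not modelled;
primers are exact oligos.

Amplicon sizing for the intron-6 poly-T repeat follows the capillary
electrophoresis genotyping convention: expected size = 179 bp of fixed
flank + the poly-T tract length, binned S (<= 198 bp), L (199-208 bp),
VL (>= 209 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .discrimination import AssayDesign, Primer
from .seqio import SequenceRecord, reverse_complement

#: fixed flanking sequence around the poly-T tract in the genotyping amplicon
POLYT_FLANK_BP = 179
#: genotype bin edges on observed amplicon size (bp)
POLYT_S_MAX = 198
POLYT_L_MAX = 208

#: mismatch weights by offset from the 3' end
DEFAULT_WEIGHTS = {0: 0.9, 1: 0.6, 2: 0.6, 3: 0.3, 4: 0.3}
DEFAULT_BODY_WEIGHT = 0.1

THETA_ROBUST = 0.5
THETA_WEAK = 0.05


def _weight_vector(length: int) -> np.ndarray:
    w = np.full(length, DEFAULT_BODY_WEIGHT)
    for off, val in DEFAULT_WEIGHTS.items():
        if off < length:
            w[off] = val
    return w  # indexed by offset from the 3' end


@dataclass
class BindingSite:
    """One primer annealing site on a template."""

    template_id: str
    strand: str  # template strand the primer extends along
    start: int  # 1-based inclusive footprint on the template
    end: int
    three_prime_pos: int
    mismatches: int
    mismatches_3prime: int  # within the last 5 bases
    mismatch_offsets: Tuple[int, ...]
    score: float


@dataclass
class AmplificationPrediction:
    assay_id: str
    template_id: str
    product_length: Optional[int]
    score: float
    call: str  # robust | weak | none
    forward_site: Optional[BindingSite] = None
    reverse_site: Optional[BindingSite] = None


def find_binding_sites(
    primer: Union[Primer, str],
    template: Union[SequenceRecord, str],
    max_total_mm: int = 3,
) -> List[BindingSite]:
    """Scan both template strands for annealing sites of *primer*.

    Sites with at most *max_total_mm* mismatches are returned; each carries
    the product-form binding score. Indels are not allowed in binding.
    """
    pseq = primer.seq if isinstance(primer, Primer) else primer
    tseq, tid = (
        (template.seq, template.id)
        if isinstance(template, SequenceRecord)
        else (template, "template")
    )
    L = len(pseq)
    if L > len(tseq):
        return []
    w = _weight_vector(L)
    tcode = np.frombuffer(tseq.encode(), dtype=np.uint8)
    sites: List[BindingSite] = []
    for strand in ("+", "-"):
        # '+': primer matches the top strand read left to right, 3' end at the
        # right edge of the footprint; '-': primer matches the bottom strand,
        # i.e. the reverse complement of the footprint, 3' end at the left edge.
        probe = pseq if strand == "+" else reverse_complement(pseq)
        pcode = np.frombuffer(probe.encode(), dtype=np.uint8)
        win = np.lib.stride_tricks.sliding_window_view(tcode, L)
        mm = win != pcode
        totals = mm.sum(axis=1)
        # offset of window column c from the primer 3' end
        offsets = (L - 1 - np.arange(L)) if strand == "+" else np.arange(L)
        for pos0 in np.nonzero(totals <= max_total_mm)[0]:
            cols = np.nonzero(mm[pos0])[0]
            offs = tuple(sorted(int(offsets[c]) for c in cols))
            score = float(np.prod(1.0 - w[list(offs)])) if offs else 1.0
            start, end = int(pos0) + 1, int(pos0) + L
            sites.append(
                BindingSite(
                    template_id=tid,
                    strand=strand,
                    start=start,
                    end=end,
                    three_prime_pos=end if strand == "+" else start,
                    mismatches=int(totals[pos0]),
                    mismatches_3prime=sum(1 for o in offs if o < 5),
                    mismatch_offsets=offs,
                    score=score,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplification(
    assay: AssayDesign,
    template: Union[SequenceRecord, str],
    theta_robust: float = THETA_ROBUST,
    theta_weak: float = THETA_WEAK,
    max_product: int = 2000,
    max_total_mm: int = 3,
) -> AmplificationPrediction:
    """Predict whether *assay* amplifies *template*.

    A product requires one primer bound on ``+`` and the other on ``-``
    with 3' ends facing (plus-strand footprint left of the minus-strand
    footprint) and a product no longer than *max_product* and no shorter
    than either primer footprint. The best pair by combined score
    ``min(forward, reverse)`` wins; ties resolve to the shortest product.
    Calls: ``robust`` if score >= *theta_robust*, ``none`` if below
    *theta_weak* or no compatible pair, else ``weak``.
    """
    tid = template.id if isinstance(template, SequenceRecord) else "template"
    f_sites = find_binding_sites(assay.forward, template, max_total_mm)
    r_sites = find_binding_sites(assay.reverse, template, max_total_mm)
    best: Optional[Tuple[float, int, int, BindingSite, BindingSite]] = None
    for plus, minus in (
        ([s for s in f_sites if s.strand == "+"], [s for s in r_sites if s.strand == "-"]),
        ([s for s in r_sites if s.strand == "+"], [s for s in f_sites if s.strand == "-"]),
    ):
        for fp in plus:
            for rp in minus:
                if rp.start < fp.start or rp.end < fp.end:
                    continue
                product = rp.end - fp.start + 1
                if product > max_product:
                    continue
                if product < max(fp.end - fp.start, rp.end - rp.start) + 1:
                    continue
                score = min(fp.score, rp.score)
                key = (-score, product, fp.start)
                if best is None or key < best[:3]:
                    best = (key[0], key[1], key[2], fp, rp)
    if best is None:
        return AmplificationPrediction(assay.id, tid, None, 0.0, "none")
    score, product = -best[0], best[1]
    if score >= theta_robust:
        call = "robust"
    elif score < theta_weak:
        call = "none"
    else:
        call = "weak"
    return AmplificationPrediction(assay.id, tid, product, score, call, best[3], best[4])


def cross_amplification_matrix(
    assays: Sequence[AssayDesign],
    templates: Sequence[SequenceRecord],
    **kwargs,
) -> pd.DataFrame:
    """Assay x template grid of amplification calls.

    Returns a DataFrame of call strings (index: assay ids, columns:
    template ids, in input order); the full predictions are attached as
    ``frame.attrs['predictions']``.
    """
    if not assays:
        raise ValueError("at least one assay required")
    calls: Dict[str, Dict[str, str]] = {}
    preds: Dict[Tuple[str, str], AmplificationPrediction] = {}
    for assay in assays:
        row = {}
        for tmpl in templates:
            p = predict_amplification(assay, tmpl, **kwargs)
            row[tmpl.id] = p.call
            preds[(assay.id, tmpl.id)] = p
        calls[assay.id] = row
    frame = pd.DataFrame.from_dict(calls, orient="index", dtype="object")
    frame = frame.reindex(index=[a.id for a in assays], columns=[t.id for t in templates])
    frame.attrs["predictions"] = preds
    return frame


def render_call_table(matrix: pd.DataFrame) -> str:
    """Plain-text heat table of calls (## robust, +  weak, .  none)."""
    sym = {"robust": "##", "weak": "+ ", "none": ". "}
    width = max((len(str(i)) for i in matrix.index), default=8) + 2
    lines = [" " * width + "  ".join(f"{c:>8.8}" for c in matrix.columns)]
    for aid, row in matrix.iterrows():
        lines.append(f"{aid:<{width}.{width}}" + "  ".join(f"{sym[v]:>8}" for v in row))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# poly-T amplicon sizing


@dataclass(frozen=True)
class PolyTCall:
    observed_size_bp: int
    bin: str  # S | L | VL
    inferred_polyt_length: int


def expected_amplicon_size(polyt_length: int) -> int:
    """Expected genotyping amplicon size: fixed 179-bp flank + tract length."""
    if polyt_length < 0:
        raise ValueError("poly-T length cannot be negative")
    return POLYT_FLANK_BP + polyt_length


def classify_polyt(observed_size_bp: int) -> PolyTCall:
    """Bin an observed amplicon size into the S / L / VL genotype classes."""
    size = int(observed_size_bp)
    if size < POLYT_FLANK_BP:
        raise ValueError(f"size {size} bp below flank length {POLYT_FLANK_BP} bp")
    if size <= POLYT_S_MAX:
        label = "S"
    elif size <= POLYT_L_MAX:
        label = "L"
    else:
        label = "VL"
    return PolyTCall(size, label, size - POLYT_FLANK_BP)
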