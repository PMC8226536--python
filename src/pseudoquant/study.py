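"""End-to-end workflow on the synthetic parent/pseudogene system.

``build_study`` runs the whole method in one call: generate the genome,
rediscover and classify the homologous loci, design all three assay
classes, and predict cross-amplification of every assay against every
template. It is the backbone of the examples and of the specificity
checks: the expected qualitative pattern is

* the splice-junction (total-pool) assay amplifies the parent cDNA *and*
  every intronless pseudogene template;
* the intron-targeted assays amplify only templates that contain intron
  sequence (the parent pre-mRNA), never a pseudogene;
* each pseudogene-specific allele assay amplifies its own template
  robustly and everything else weakly at best (the "leaky" 3'-mismatch
  signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .discrimination import (
    AssayDesign,
    PrimerConstraints,
    align_to_target,
    design_junction_assay,
    design_primary_transcript_assay,
    find_discriminating_sites,
    pair_allele_specific_assay,
)
from .homology import (
    HomologyHit,
    LocusClassification,
    catalog_report,
    classify_locus,
    find_homologous_loci,
)
from .insilico_pcr import cross_amplification_matrix
from .seqio import SequenceRecord
from .synthetic import LocusSet, default_locus_config, generate_locus_set

#: permissive envelope used for the synthetic system (random sequence has no
#: reason to offer many 57-63 C candidates at every discriminating site)
WIDE_CONSTRAINTS = PrimerConstraints(tm_min=50.0, tm_max=70.0, gc_min=0.25, gc_max=0.75)


@dataclass
class StudySystem:
    locus_set: LocusSet
    hits: List[HomologyHit]
    classifications: List[LocusClassification]
    catalog: pd.DataFrame
    templates: Dict[str, SequenceRecord]
    pre_mrna: SequenceRecord
    assays: Dict[str, AssayDesign]
    junction_matrix: pd.DataFrame
    intron_matrix: pd.DataFrame
    allele_matrix: pd.DataFrame


def _match_truth(hit: HomologyHit, truth: pd.DataFrame) -> Optional[str]:
    for _, row in truth.iterrows():
        if hit.target.chrom == row["chrom"] and not (
            hit.target.end < row["start"] or hit.target.start > row["end"]
        ):
            return str(row["name"])
    return None


def build_study(seed: int = 17, include_paralog: bool = True) -> StudySystem:
    """Run discovery, classification, assay design and in-silico PCR."""
    ls = generate_locus_set(default_locus_config(seed, include_paralog))
    hits = find_homologous_loci(ls.cdna, ls.genome)
    classifications = [
        classify_locus(
            h, ls.gene_model, ls.cds, ls.genome, cdna=ls.cdna,
            name=_match_truth(h, ls.truth),
        )
        for h in hits
    ]
    catalog = catalog_report(classifications)

    pseudo_names = list(ls.truth.loc[ls.truth["class"] == "pseudogene", "name"])
    templates: Dict[str, SequenceRecord] = {ls.cdna.id: ls.cdna}
    for name in pseudo_names:
        templates[name] = ls.planted_sequence(name)
    parent_row = ls.truth.set_index("name").loc["parent"]
    pre_mrna = SequenceRecord(
        "pre_mrna",
        ls.chrom("chr_parent")[int(parent_row["start"]) - 1 : int(parent_row["end"])],
    )

    assays: Dict[str, AssayDesign] = {}
    pseudo_templates = [templates[n] for n in pseudo_names]
    # total-pool junction assay: conserved across the homolog family
    assays["junction_total"] = design_junction_assay(
        ls.gene_model, ls.cdna, (4, 5), WIDE_CONSTRAINTS,
        homologs=pseudo_templates, assay_id="junction_total",
    )
    # primary-transcript surrogates
    assays["exon_intron_6"] = design_primary_transcript_assay(
        ls.gene_model, ls.chrom("chr_parent"), "exon_intron", 6,
        WIDE_CONSTRAINTS, assay_id="exon_intron_6",
    )
    assays["intra_intron_9"] = design_primary_transcript_assay(
        ls.gene_model, ls.chrom("chr_parent"), "intra_intron", 9,
        WIDE_CONSTRAINTS, assay_id="intra_intron_9",
    )
    # one allele-specific assay per pseudogene, designed on its own template
    for name in pseudo_names:
        others = [ls.cdna] + [templates[n] for n in pseudo_names if n != name]
        table = align_to_target(templates[name], others)
        sites = find_discriminating_sites(table, "unique_to_target")
        assays[f"as_{name}"] = pair_allele_specific_assay(
            templates[name], sites, WIDE_CONSTRAINTS, assay_id=f"as_{name}"
        )

    cdna_panel = [ls.cdna] + pseudo_templates
    junction_matrix = cross_amplification_matrix([assays["junction_total"]], cdna_panel)
    intron_matrix = cross_amplification_matrix(
        [assays["exon_intron_6"], assays["intra_intron_9"]],
        cdna_panel + [pre_mrna],
    )
    allele_matrix = cross_amplification_matrix(
        [assays[f"as_{n}"] for n in pseudo_names], cdna_panel
    )
    return StudySystem(
        locus_set=ls,
        hits=hits,
        classifications=classifications,
        catalog=catalog,
        templates=templates,
        pre_mrna=pre_mrna,
        assays=assays,
        junction_matrix=junction_matrix,
        intron_matrix=intron_matrix,
        allele_matrix=allele_matrix,
    )


def specificity_summary(study: StudySystem) -> Dict[str, bool]:
    """Boolean digest of the expected qualitative specificity pattern."""
    jm = study.junction_matrix
    cdna_id = study.locus_set.cdna.id
    pseudo = [c for c in jm.columns if c != cdna_id]
    junction_all = all(jm.loc["junction_total", t] in ("robust", "weak") for t in jm.columns)
    im = study.intron_matrix
    intron_clean = all(
        im.loc[a, t] == "none"
        for a in im.index
        for t in pseudo + [cdna_id]
    )
    intron_premrna = all(im.loc[a, "pre_mrna"] == "robust" for a in im.index)
    am = study.allele_matrix
    own_robust = all(am.loc[f"as_{n}", n] == "robust" for n in pseudo)
    leaky = all(
        am.loc[f"as_{n}", t] in ("weak", "none")
        for n in pseudo
        for t in am.columns
        if t != n
    )
    return {
        "junction_amplifies_all_templates": junction_all,
        "intron_assays_silent_on_intronless": intron_clean,
        "intron_assays_amplify_pre_mrna": intron_premrna,
        "allele_specific_own_template_robust": own_robust,
        "allele_specific_leaky_on_others": leaky,
    }
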