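"""Cross-referencing disease credible sets with eQTL credible sets and
regulatory annotations.

Disease and expression fine-mapping run over one shared variant namespace,
so credible-set overlap is an exact id intersection per (disease CS,
eQTL CS) pair.  Regulatory annotation is plain interval overlap: a variant
hits an interval when its 0-based position falls in the half-open
[start, end) range, optionally padded by a slop and filtered to selected
annotation labels (e.g. enhancer chromatin states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import IntervalSet, VariantRecord
from .susie import CredibleSet


@dataclass
class OverlapPair:
    disease_cs: str
    eqtl_cs: str
    shared_ids: list[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_ids)


@dataclass
class OverlapReport:
    pairs: list[OverlapPair] = field(default_factory=list)
    n_disease_variants: int = 0
    n_eqtl_variants: int = 0
    n_shared_total: int = 0  # distinct ids appearing in any overlapping pair


def credible_set_overlap(
    disease_css: dict[str, CredibleSet | Sequence[str]],
    eqtl_css: dict[str, CredibleSet | Sequence[str]],
) -> OverlapReport:
    """Exact variant-id intersection for every (disease, eQTL) CS pair.

    Inputs map a set label (e.g. "COA_classII_CS1", "HLA-DQA1_LCL_CS1") to a
    credible set or a plain id collection.  Pairs with an empty intersection
    are omitted; totals count distinct variant ids.
    """

    def ids_of(cs) -> list[str]:
        return list(cs.variant_ids) if isinstance(cs, CredibleSet) else list(cs)

    disease = {k: set(ids_of(v)) for k, v in disease_css.items()}
    eqtl = {k: set(ids_of(v)) for k, v in eqtl_css.items()}
    pairs: list[OverlapPair] = []
    shared_union: set[str] = set()
    for dk in sorted(disease):
        for ek in sorted(eqtl):
            shared = sorted(disease[dk] & eqtl[ek])
            if shared:
                pairs.append(OverlapPair(dk, ek, shared))
                shared_union.update(shared)
    return OverlapReport(
        pairs=pairs,
        n_disease_variants=len(set().union(*disease.values())) if disease else 0,
        n_eqtl_variants=len(set().union(*eqtl.values())) if eqtl else 0,
        n_shared_total=len(shared_union),
    )


@dataclass
class AnnotationHit:
    variant_id: str
    chrom: str
    pos: int  # 1-based variant position
    interval_start: int
    interval_end: int
    label: str


def annotate_variants(
    variants: Sequence[VariantRecord],
    intervals: IntervalSet,
    labels_filter: Sequence[str] = (),
    slop: int = 0,
) -> list[AnnotationHit]:
    """Interval overlap of variants against an annotation track.

    A variant hits an interval when its 0-based position (pos - 1) lies in
    [start - slop, end + slop); one record per (variant, interval) pair.
    ``labels_filter`` restricts hits to the named annotation states.
    """
    wanted = set(labels_filter)
    hits: list[AnnotationHit] = []
    for v in variants:
        p0 = v.pos - 1
        for iv in intervals:
            if wanted and iv.label not in wanted:
                continue
            if iv.chrom == v.chrom and iv.start - slop <= p0 < iv.end + slop:
                hits.append(
                    AnnotationHit(
                        variant_id=v.id,
                        chrom=v.chrom,
                        pos=v.pos,
                        interval_start=iv.start,
                        interval_end=iv.end,
                        label=iv.label,
                    )
                )
    return hits
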