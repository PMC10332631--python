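"""Gene-neighborhood analysis: cluster detection, canonical arrangements, synteny.

A gene cluster is a maximal run of genes bearing labels of interest on
one contig, where consecutive labelled genes are separated by at most
``max_gap`` unlabelled genes.  Arrangements are rendered as canonical
label strings (read along the majority strand) so that, e.g., a
lipS1-lpl(AB)-lipT-lipS2 operon gives the same string regardless of
which strand it was drawn on.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .model import DomainOrder, FunctionalAnnotation, GeneCluster, GeneRecord, Label

DEFAULT_MAX_GAP = 3


def label_token(annotation: FunctionalAnnotation) -> str:
    """Canonical lower-camel arrangement token for one annotated gene."""
    label = annotation.label
    if label is Label.LPL:
        if annotation.has_lplB_domain:
            return "lpl(AB)" if annotation.domain_order is DomainOrder.A_THEN_B else "lpl(BA)"
        return "lplA"
    if label is Label.LPLB:
        return "lplB"
    if label is Label.NONE:
        return "."
    # lipA, lipS1, gcvH, sHdr -> first letter lower-cased
    return label.value[0].lower() + label.value[1:]


def find_clusters(
    genes: Sequence[GeneRecord],
    annotations: Mapping[str, FunctionalAnnotation],
    labels_of_interest: Iterable[Label] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[GeneCluster]:
    """Partition labelled genes into neighborhood clusters.

    ``genes`` must be sorted by (contig_id, gene_index).  Every labelled
    gene (label in ``labels_of_interest``; default: any non-NONE label)
    ends up in exactly one cluster; unlabelled genes only contribute to
    gap counting.
    """
    wanted = set(labels_of_interest) if labels_of_interest is not None else None

    def is_labelled(g: GeneRecord) -> bool:
        ann = annotations.get(g.protein_id)
        if ann is None or ann.label is Label.NONE:
            return False
        return wanted is None or ann.label in wanted

    clusters: list[GeneCluster] = []
    current: list[tuple[GeneRecord, FunctionalAnnotation]] = []
    prev: GeneRecord | None = None
    for gene in genes:
        if not is_labelled(gene):
            continue
        if current and prev is not None:
            same_contig = gene.contig_id == prev.contig_id and gene.genome_id == prev.genome_id
            gap = gene.gene_index - prev.gene_index - 1
            if not same_contig or gap > max_gap:
                clusters.append(
                    GeneCluster(current[0][0].genome_id, current[0][0].contig_id, current)
                )
                current = []
        current.append((gene, annotations[gene.protein_id]))
        prev = gene
    if current:
        clusters.append(GeneCluster(current[0][0].genome_id, current[0][0].contig_id, current))
    return clusters


def arrangement_string(cluster: GeneCluster) -> str:
    """Canonical arrangement: tokens joined in reading order.

    If the majority of member genes lie on the minus strand, the member
    order is reversed before joining, so a cluster and its reverse
    complement render identically.  Strand ties keep as-read order.
    """
    if not cluster.members:
        raise ValueError("empty cluster has no arrangement")
    members = list(cluster.members)
    minus = sum(1 for g, _ in members if g.strand == "-")
    if minus * 2 > len(members):
        members = members[::-1]
    return "-".join(label_token(ann) for _, ann in members)


def is_syntenic(
    genes: Sequence[GeneRecord],
    annotations: Mapping[str, FunctionalAnnotation],
    label_a: Label,
    label_b: Label,
    max_gap: int = DEFAULT_MAX_GAP,
) -> bool:
    """True iff some cluster of this genome contains both labels."""
    for cluster in find_clusters(genes, annotations, {label_a, label_b}, max_gap):
        labels = set(cluster.labels())
        if label_a in labels and label_b in labels:
            return True
    return False


# ---------------------------------------------------------------------------
# I/O


def read_gff3(path: str | Path, genome_id: str | None = None) -> list[GeneRecord]:
    """Load CDS features from a GFF3 file as ordered GeneRecords.

    ``protein_id`` is taken from the ``ID`` attribute (fallback
    ``locus_tag``); ``gene_index`` numbers genes along each contig by
    start coordinate.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    gid = genome_id if genome_id is not None else Path(path).stem
    per_contig: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        per_contig.setdefault(feat.seqid, []).append(feat)
    records: list[GeneRecord] = []
    for contig in sorted(per_contig):
        feats = sorted(per_contig[contig], key=lambda f: (f.start, f.end))
        for idx, feat in enumerate(feats):
            pid = feat.attributes.get("ID", feat.attributes.get("locus_tag", [None]))[0]
            if pid is None:
                raise ValueError(f"{path}: CDS at {contig}:{feat.start} lacks ID/locus_tag")
            records.append(
                GeneRecord(
                    genome_id=gid,
                    contig_id=contig,
                    gene_index=idx,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in ("+", "-") else "+",
                    protein_id=pid,
                )
            )
    return records


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": c.genome_id,
            "contig_id": c.contig_id,
            "arrangement": arrangement_string(c),
            "n_members": len(c),
            "protein_ids": ",".join(c.protein_ids()),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "arrangement", "n_members", "protein_ids"]
    )


def write_clusters_tsv(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)
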