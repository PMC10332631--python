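"""End-to-end pipeline: annotate -> cluster -> profile -> type -> stats -> datasets.

``run_all`` is a pure function of its inputs and configuration: outputs
contain no timestamps, and the run log records versions, parameters and
input checksums, so re-running the same config yields byte-identical
output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__, annotate, context, phyloprep, profiles, stats
from .catalog import load_catalog
from .model import Label, Provenance

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run; JSON round-trippable."""

    faa: str
    domtbl: str
    gff: str
    taxonomy: str
    out_dir: str
    catalog: str | None = None
    max_gap: int = context.DEFAULT_MAX_GAP
    identity_threshold: float = 0.7
    seed: int = 0
    syntenic_whitelist: list[str] = field(default_factory=list)
    tool_config: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("faa", "domtbl", "gff", "taxonomy"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"config.{name}: {path} does not exist")
        if self.catalog is not None and not Path(self.catalog).exists():
            raise FileNotFoundError(f"config.catalog: {self.catalog} does not exist")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Any stage failure aborts with the stage name and offending record in
    the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(config.catalog)

    def stage(name):
        logger.info("stage: %s", name)

    # --- annotate -------------------------------------------------------
    stage("annotate")
    try:
        protein_ids = annotate.read_fasta_ids(config.faa)
        sequences = annotate.read_fasta_sequences(config.faa)
        hits = annotate.read_domtblout(config.domtbl, catalog)
        annotations = annotate.annotate_proteome(protein_ids, hits, catalog)
    except Exception as exc:
        raise RuntimeError(f"stage annotate failed: {exc}") from exc
    annotate.write_annotations_tsv(annotations, out / "annotations.tsv")

    # --- context --------------------------------------------------------
    stage("cluster")
    genes = context.read_gff3(config.gff)
    genes_by_genome: dict[str, list] = {}
    for g in genes:
        genes_by_genome.setdefault(g.genome_id, []).append(g)
    # GFF written by the simulator encodes genome in the attribute;
    # contig-derived genome ids fall back to contig prefix before "_c".
    if len(genes_by_genome) == 1 and "_c" in genes[0].contig_id:
        genes_by_genome = {}
        for g in genes:
            gid = g.contig_id.rsplit("_c", 1)[0]
            genes_by_genome.setdefault(gid, []).append(
                type(g)(gid, g.contig_id, g.gene_index, g.start, g.end, g.strand, g.protein_id)
            )
    all_clusters = []
    clusters_by_genome: dict[str, list] = {}
    for gid in sorted(genes_by_genome):
        glist = sorted(genes_by_genome[gid], key=lambda g: (g.contig_id, g.gene_index))
        genes_by_genome[gid] = glist
        cl = context.find_clusters(glist, annotations, max_gap=config.max_gap)
        clusters_by_genome[gid] = cl
        all_clusters.extend(cl)
    context.write_clusters_tsv(all_clusters, out / "clusters.tsv")

    # --- typing ---------------------------------------------------------
    stage("typecall")
    metadata = profiles.read_gtdb_metadata(config.taxonomy)
    tax_map = profiles.taxonomy_map(metadata)
    anns_by_genome = {
        gid: {g.protein_id: annotations[g.protein_id] for g in genes_by_genome[gid]}
        for gid in genes_by_genome
    }
    cohort_profiles = profiles.build_profiles(anns_by_genome, tax_map)
    profiles.write_profiles_tsv(cohort_profiles, out / "profiles.tsv")
    pathway_calls = [profiles.call_pathways(p) for p in cohort_profiles]
    profiles.pathway_calls_to_frame(pathway_calls).to_csv(
        out / "pathway_calls.tsv", sep="\t", index=False
    )
    ligase_calls = []
    for p in cohort_profiles:
        calls = profiles.classify_ligases(
            p, clusters_by_genome.get(p.genome_id, []), anns_by_genome[p.genome_id],
            genes_by_genome.get(p.genome_id),
        )
        ligase_calls.extend(
            {"genome_id": p.genome_id, "protein_id": c.protein_id,
             "subtype": c.subtype.value, "rationale": ",".join(c.rationale)}
            for c in calls
        )
    import pandas as pd

    pd.DataFrame(
        ligase_calls, columns=["genome_id", "protein_id", "subtype", "rationale"]
    ).to_csv(out / "ligase_calls.tsv", sep="\t", index=False)

    # --- stats ----------------------------------------------------------
    stage("stats")
    report = {}
    for domain in ("Bacteria", "Archaea"):
        dom_profiles = [p for p in cohort_profiles if p.domain == domain]
        if not dom_profiles:
            continue
        venn = stats.venn_counts(dom_profiles, ["Lpl", "LipB", "LipM", "LipA", "LipS1S2"], domain)
        stats.venn_to_frame(venn).to_csv(
            out / f"venn_{domain.lower()}.tsv", sep="\t", index=False
        )
        stats.phylum_table_to_frame(
            stats.phylum_table(dom_profiles, list(stats.FLAG_NAMES))
        ).to_csv(out / f"phylum_{domain.lower()}.tsv", sep="\t", index=False)
        report[domain] = {
            "n_genomes": len(dom_profiles),
            **stats.cooccurrence_report(dom_profiles),
        }
    (out / "cooccurrence.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    # --- phylo datasets -------------------------------------------------
    stage("dataset")
    pool = build_record_pool(
        cohort_profiles, anns_by_genome, clusters_by_genome, genes_by_genome,
        sequences, hits, config,
    )
    datasets_dir = out / "datasets"
    datasets_dir.mkdir(exist_ok=True)
    tool_cfg = phyloprep.PhyloToolConfig(seed=config.seed, **config.tool_config)
    for name in phyloprep.DATASET_NAMES:
        try:
            records, manifest = phyloprep.build_dataset(name, pool)
        except ValueError as exc:
            logger.warning("dataset %s not built: %s", name, exc)
            continue
        phyloprep.write_fasta(records, datasets_dir / f"{name}.faa")
        phyloprep.write_partition_tsv(records, datasets_dir / f"{name}.partitions.tsv")
        manifest.to_tsv(datasets_dir / f"{name}.manifest.tsv")
        cmds = phyloprep.emit_tool_manifest(name, records, tool_cfg, workdir="datasets")
        phyloprep.write_tool_manifest(cmds, datasets_dir / f"{name}.commands.sh")

    # --- run log --------------------------------------------------------
    log = {
        "lipomap_version": __version__,
        "config": asdict(config),
        "inputs_sha256": {
            "faa": _sha256(config.faa),
            "domtbl": _sha256(config.domtbl),
            "gff": _sha256(config.gff),
            "taxonomy": _sha256(config.taxonomy),
        },
        "n_proteins": len(protein_ids),
        "n_hits": len(hits),
        "n_genomes": len(cohort_profiles),
        "n_clusters": len(all_clusters),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out


def build_record_pool(
    cohort_profiles,
    anns_by_genome,
    clusters_by_genome,
    genes_by_genome,
    sequences,
    hits,
    config: RunConfig,
) -> phyloprep.RecordPool:
    """Assemble all phylogenetic record families from annotated genomes."""
    from .model import DomainOrder, PhyloRecord

    pool = phyloprep.RecordPool()
    hits_by_protein: dict[str, list] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    whitelist = frozenset(config.syntenic_whitelist)

    def native(pid: str, label: Label, provenance=Provenance.NATIVE) -> PhyloRecord:
        seq = sequences[pid]
        return PhyloRecord(
            record_id=pid, sequence=seq, partitions=((label.value, 1, len(seq)),),
            provenance=provenance, label=label,
        )

    all_medians = phyloprep.median_label_lengths(
        {pid: a for anns in anns_by_genome.values() for pid, a in anns.items()}, sequences
    )

    for p in sorted(cohort_profiles, key=lambda p: p.genome_id):
        anns = anns_by_genome[p.genome_id]
        clusters = clusters_by_genome.get(p.genome_id, [])
        for pid in sorted(anns):
            a = anns[pid]
            if a.label is Label.LPL and a.has_lplB_domain:
                if a.domain_order is DomainOrder.B_THEN_A:
                    phits = hits_by_protein.get(pid, [])
                    lplb = [h for h in phits if h.hmm_acc != a.best_hit.hmm_acc and h.above_cutoff]
                    rec = native(pid, Label.LPL)
                    if lplb:
                        boundary = phyloprep.cp_boundary_from_envelopes(
                            min(lplb, key=lambda h: h.env_from), a.best_hit
                        )
                        rec = phyloprep.cp_normalize(rec, boundary)
                    pool.ligases.append(rec)
                else:
                    pool.ligases.append(native(pid, Label.LPL))
            elif a.label is Label.LIPB:
                pool.lipB.append(native(pid, Label.LIPB))
            elif a.label is Label.LIPM:
                pool.lipM.append(native(pid, Label.LIPM))
            elif a.label is Label.LIPS1 and p.count(Label.LIPS1) == 1:
                pool.lipS1.append(native(pid, Label.LIPS1))
            elif a.label is Label.LIPS2 and p.count(Label.LIPS2) == 1:
                pool.lipS2.append(native(pid, Label.LIPS2))
            elif a.label is Label.BIRA:
                pool.outgroups.setdefault("BirA", []).append(native(pid, Label.BIRA, Provenance.OUTGROUP))
            elif a.label is Label.BIOB:
                pool.outgroups.setdefault("BioB", []).append(native(pid, Label.BIOB, Provenance.OUTGROUP))
        concat = phyloprep.concat_syntenic_pair(
            p.genome_id, anns, clusters, sequences, whitelist
        )
        if concat is not None:
            pool.ligases.append(concat)
        s12 = phyloprep.concat_lipS1S2(p, anns, sequences, all_medians)
        if s12 is not None:
            pool.lipS1S2.append(s12)
        # clade-2 rooting set: classical ligases (LipA-containing
        # genomes without the LipS1/S2 pair)
        if p.flag("LipA") and not p.flag("LipS1S2"):
            for pid in sorted(anns):
                if anns[pid].label is Label.LPL:
                    pool.outgroups.setdefault("clade2", []).append(
                        native(pid, Label.LPL, Provenance.OUTGROUP)
                    )

    if len(pool.lipB) + len(pool.lipM) > 4:
        pool.lipB = phyloprep.cluster_by_similarity(pool.lipB, config.identity_threshold) if pool.lipB else []
        pool.lipM = phyloprep.cluster_by_similarity(pool.lipM, config.identity_threshold) if pool.lipM else []
    for key in pool.outgroups:
        pool.outgroups[key] = pool.outgroups[key][:5]
    return pool
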