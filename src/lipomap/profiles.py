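"""Per-genome presence/absence profiles, ligase subtype calls, pathway typing.

The profile HMMs label every detected lipoate:protein ligase uniformly
as Lpl; the distinguishing features between classical ligases and the
sulfur-oxidizer-associated sLpl(AB) subtype are the genomic context
(co-clustering with lipS1/lipS2) and the type of lipoate synthase the
genome carries (LipA vs the LipS1/S2 pair).  Pathway systems combine a
first-step enzyme (ligase or octanoyltransferase) with a lipoyl
synthase; genomes with a ligase but no synthase can only scavenge
preformed lipoate.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .context import is_syntenic
from .model import (
    FLAG_NAMES,
    GTDB_RANKS,
    DomainOrder,
    FunctionalAnnotation,
    GeneCluster,
    GeneRecord,
    GenomeProfile,
    Label,
    LigaseCall,
    LigaseSubtype,
    PathwayCall,
    PathwaySystem,
)

logger = logging.getLogger(__name__)

_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_gtdb_taxonomy(taxonomy: str) -> dict[str, str]:
    """Parse a GTDB taxonomy string ``d__...;p__...;...;s__...``.

    Raises ValueError on malformed strings (wrong rank count, wrong
    prefixes, or a domain other than Bacteria/Archaea).
    """
    parts = [p.strip() for p in taxonomy.strip().split(";")]
    if len(parts) != len(_RANK_PREFIXES):
        raise ValueError(f"expected {len(_RANK_PREFIXES)} ranks, got {len(parts)}: {taxonomy!r}")
    out: dict[str, str] = {}
    for rank, prefix, part in zip(GTDB_RANKS, _RANK_PREFIXES, parts):
        if not part.startswith(prefix):
            raise ValueError(f"rank {rank} must start with {prefix!r}: {part!r}")
        out[rank] = part[len(prefix):]
    if out["domain"] not in ("Bacteria", "Archaea"):
        raise ValueError(f"unknown domain {out['domain']!r}")
    return out


def build_profile(
    genome_id: str,
    annotations: Mapping[str, FunctionalAnnotation] | Iterable[FunctionalAnnotation],
    taxonomy: str,
) -> GenomeProfile:
    """Aggregate one genome's annotations into a presence/absence profile."""
    if isinstance(annotations, Mapping):
        anns = list(annotations.values())
    else:
        anns = list(annotations)
    counts = Counter(a.label for a in anns if a.label is not Label.NONE)
    return GenomeProfile(
        genome_id=genome_id,
        taxonomy=parse_gtdb_taxonomy(taxonomy),
        counts=dict(counts),
    )


def build_profiles(
    annotations_by_genome: Mapping[str, Mapping[str, FunctionalAnnotation]],
    taxonomy_by_genome: Mapping[str, str],
) -> list[GenomeProfile]:
    """Profiles for a cohort; genomes with malformed taxonomy are excluded with a warning."""
    profiles = []
    for gid in sorted(annotations_by_genome):
        tax = taxonomy_by_genome.get(gid)
        if tax is None:
            logger.warning("genome %s has no taxonomy row; excluded", gid)
            continue
        try:
            profiles.append(build_profile(gid, annotations_by_genome[gid], tax))
        except ValueError as exc:
            logger.warning("genome %s excluded: %s", gid, exc)
    return profiles


# ---------------------------------------------------------------------------
# Ligase subtype classification


def classify_ligases(
    profile: GenomeProfile,
    clusters: Sequence[GeneCluster],
    annotations: Mapping[str, FunctionalAnnotation],
    genes: Sequence[GeneRecord] | None = None,
) -> list[LigaseCall]:
    """Subtype every Lpl-labelled protein of one genome from its context.

    Decision order per ligase: a circularly permuted fusion (B-then-A
    architecture) is cpLpl_BA; an unfused catalytic domain with a
    syntenic LplB gene is the bipartite form; a ligase co-clustered with
    lipS1/lipS2, or the sole ligase of a genome whose synthase is the
    LipS1/S2 pair, is sLpl_AB; a ligase in a LipA-containing genome
    without LipS1/S2 is the classical form; anything else is
    undetermined.
    """
    ligases = sorted(
        pid for pid, a in annotations.items() if a.label is Label.LPL
    )
    cluster_of: dict[str, GeneCluster] = {}
    for c in clusters:
        for pid in c.protein_ids():
            cluster_of[pid] = c

    calls: list[LigaseCall] = []
    n_ligases = profile.count(Label.LPL)
    for pid in ligases:
        ann = annotations[pid]
        rationale: list[str] = []
        in_s_cluster = False
        c = cluster_of.get(pid)
        if c is not None and ({Label.LIPS1, Label.LIPS2} & set(c.labels())):
            in_s_cluster = True
            rationale.append("context_with_lipS1S2")
        if ann.has_lplB_domain:
            rationale.append("fused")

        if ann.domain_order is DomainOrder.B_THEN_A:
            calls.append(LigaseCall(pid, LigaseSubtype.CPLPL_BA, tuple(rationale + ["permuted"])))
            continue
        if not ann.has_lplB_domain and genes is not None and is_syntenic(
            genes, annotations, Label.LPL, Label.LPLB
        ):
            calls.append(
                LigaseCall(pid, LigaseSubtype.BIPARTITE_LPLAB, tuple(rationale + ["syntenic_pair"]))
            )
            continue
        if in_s_cluster:
            calls.append(LigaseCall(pid, LigaseSubtype.SLPL_AB, tuple(rationale)))
            continue
        if profile.flag("LipS1S2") and n_ligases == 1:
            rationale.append("cooccurring_synthase_LipS1S2")
            calls.append(LigaseCall(pid, LigaseSubtype.SLPL_AB, tuple(rationale)))
            continue
        if profile.flag("LipA") and not profile.flag("LipS1S2"):
            rationale.append("cooccurring_synthase_LipA")
            calls.append(LigaseCall(pid, LigaseSubtype.CLASSICAL_LPL, tuple(rationale)))
            continue
        calls.append(LigaseCall(pid, LigaseSubtype.UNDETERMINED, ()))
    return calls


# ---------------------------------------------------------------------------
# Pathway-system calling


def call_pathways(profile: GenomeProfile) -> PathwayCall:
    """Call the lipoate assembly systems a genome can run from its profile.

    A system pairs a first-step enzyme with a synthase: LipB/LipA,
    LipM/LipA, Lpl/LipA, sLpl/LipS1S2, and LipM/LipS1S2 (the
    ligase-independent variant, only called when no ligase is present).
    A ligase without any synthase yields scavenging-only.
    """
    has = profile.flag
    systems: set[PathwaySystem] = set()
    if has("LipB") and has("LipA"):
        systems.add(PathwaySystem.LIPB_LIPA)
    if has("LipM") and has("LipA"):
        systems.add(PathwaySystem.LIPM_LIPA)
    if has("Lpl") and has("LipA"):
        systems.add(PathwaySystem.LPL_LIPA)
    if has("Lpl") and has("LipS1S2"):
        systems.add(PathwaySystem.SLPL_LIPS1S2)
    if has("LipM") and has("LipS1S2") and not has("Lpl"):
        systems.add(PathwaySystem.LIPM_LIPS1S2)
    if has("Lpl") and not has("LipA") and not has("LipS1S2"):
        systems.add(PathwaySystem.LPL_SCAVENGING_ONLY)
    if not systems:
        systems.add(PathwaySystem.NONE)
    return PathwayCall(genome_id=profile.genome_id, systems=frozenset(systems))


# ---------------------------------------------------------------------------
# I/O


def profiles_to_frame(profiles: Sequence[GenomeProfile]) -> pd.DataFrame:
    """One row per genome: taxonomy, presence flags (0/1), copy counts."""
    rows = []
    for p in sorted(profiles, key=lambda p: p.genome_id):
        row: dict = {
            "genome_id": p.genome_id,
            "domain": p.domain,
            "phylum": p.phylum,
        }
        row.update({name: int(v) for name, v in p.flags().items()})
        for lab in Label:
            if lab is Label.NONE:
                continue
            row[f"n_{lab.value}"] = p.count(lab)
        rows.append(row)
    cols = ["genome_id", "domain", "phylum", *FLAG_NAMES] + [
        f"n_{lab.value}" for lab in Label if lab is not Label.NONE
    ]
    return pd.DataFrame(rows, columns=cols)


def write_profiles_tsv(profiles: Sequence[GenomeProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def pathway_calls_to_frame(calls: Sequence[PathwayCall]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": c.genome_id,
            "systems": ",".join(sorted(s.value for s in c.systems)),
        }
        for c in sorted(calls, key=lambda c: c.genome_id)
    ]
    return pd.DataFrame(rows, columns=["genome_id", "systems"])


def read_gtdb_metadata(path: str | Path) -> pd.DataFrame:
    """Read a GTDB metadata TSV (requires accession + gtdb_taxonomy columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"accession", "gtdb_taxonomy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GTDB metadata lacks columns: {sorted(missing)}")
    return df


def species_representatives(metadata: pd.DataFrame) -> list[str]:
    """Accessions of species-cluster representative genomes.

    Uses the ``gtdb_representative`` column (t/f) when present;
    otherwise keeps the first genome of each species name.  This is the
    input manifest for a one-representative-per-species analysis.
    """
    if "gtdb_representative" in metadata.columns:
        mask = metadata["gtdb_representative"].str.lower().isin(("t", "true", "1"))
        return metadata.loc[mask, "accession"].tolist()
    species = metadata["gtdb_taxonomy"].str.split(";").str[-1]
    return metadata.loc[~species.duplicated(), "accession"].tolist()


def taxonomy_map(metadata: pd.DataFrame) -> dict[str, str]:
    return dict(zip(metadata["accession"], metadata["gtdb_taxonomy"]))
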