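"""Taxon-normalized co-occurrence statistics over presence/absence profiles.

Three summaries: exact Venn-region counts for up to five features,
conditional co-occurrence percentages (the "X% of genomes with A also
have B" numbers), and per-phylum feature percentages normalized to
phylum size.  Bacteria and Archaea are always summarized separately;
percentages are over species-representative genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .model import FLAG_NAMES, GenomeProfile

FlagExpr = str | Callable[[Mapping[str, bool]], bool]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at the given decimal (paper-style 74.3%, 91%)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percentage(value: float) -> str:
    """One-decimal half-up; integral values print without a decimal."""
    r = round_half_up(value, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


# ---------------------------------------------------------------------------
# Input adapters


def profiles_to_flag_frame(profiles: Sequence[GenomeProfile]) -> pd.DataFrame:
    """Boolean flag matrix (one row per genome) with domain/phylum columns."""
    rows = []
    for p in profiles:
        row: dict = {"genome_id": p.genome_id, "domain": p.domain, "phylum": p.phylum}
        row.update(p.flags())
        rows.append(row)
    return pd.DataFrame(rows, columns=["genome_id", "domain", "phylum", *FLAG_NAMES])


def _as_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profiles_to_flag_frame(list(profiles))


def load_presence_absence_table(
    path: str | Path,
    column_map: Mapping[str, str],
    genome_col: str = "genome_id",
    taxonomy_col: str | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Read an external presence/absence spreadsheet into the flag-frame layout.

    ``column_map`` maps flag names (``Lpl``, ``LipA``, ...) to the
    spreadsheet's column headers; cells are truthy on 1/x/yes/true.
    Supports XLSX (via openpyxl) and TSV/CSV.  Intended for
    supplementary presence/absence tables published alongside genome
    surveys.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")

    def truthy(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("1", "x", "yes", "true", "t", "+")
        try:
            return bool(int(v))
        except (TypeError, ValueError):
            return False

    out = pd.DataFrame()
    out["genome_id"] = raw[genome_col].astype(str)
    if taxonomy_col is not None:
        tax = raw[taxonomy_col].astype(str)
        out["domain"] = tax.str.extract(r"d__([^;]*)")[0].fillna("")
        out["phylum"] = tax.str.extract(r"p__([^;]*)")[0].fillna("")
    else:
        out["domain"] = raw.get("domain", "")
        out["phylum"] = raw.get("phylum", "")
    for flag in FLAG_NAMES:
        col = column_map.get(flag)
        out[flag] = raw[col].map(truthy) if col is not None else False
    if "LipS1S2" not in column_map:
        out["LipS1S2"] = out["LipS1"] & out["LipS2"]
    return out


# ---------------------------------------------------------------------------
# Venn-region counts


@dataclass
class VennSummary:
    """Exact inclusion/exclusion region counts for a feature set.

    ``regions`` maps each non-empty feature subset (frozenset of names)
    to the number of genomes having exactly those features (of the ones
    considered); genomes with none of the features are counted in
    ``n_empty``.
    """

    features: tuple[str, ...]
    regions: dict[frozenset, int]
    total_genomes: int
    n_empty: int
    domain: str = ""

    def count(self, *features: str) -> int:
        return self.regions.get(frozenset(features), 0)

    def with_feature(self, feature: str) -> int:
        """Genomes possessing ``feature`` (marginal count over regions)."""
        return sum(n for region, n in self.regions.items() if feature in region)


def venn_counts(profiles, features: Sequence[str], domain: str = "") -> VennSummary:
    """Count genomes in every inclusion/exclusion region of 1-5 features."""
    if not 1 <= len(features) <= 5:
        raise ValueError("venn_counts supports 1-5 features")
    frame = _as_frame(profiles)
    unknown = [f for f in features if f not in frame.columns]
    if unknown:
        raise KeyError(f"unknown flag name(s): {unknown}")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(features) + 1):
        for combo in combinations(features, r):
            regions[frozenset(combo)] = 0
    n_empty = 0
    for _, row in frame.iterrows():
        membership = frozenset(f for f in features if bool(row[f]))
        if membership:
            regions[membership] += 1
        else:
            n_empty += 1
    return VennSummary(
        features=tuple(features),
        regions=regions,
        total_genomes=len(frame),
        n_empty=n_empty,
        domain=domain,
    )


def venn_to_frame(summary: VennSummary) -> pd.DataFrame:
    rows = [
        {
            "region": "&".join(sorted(region)),
            "count": count,
            "pct_of_total": format_percentage(
                100.0 * count / summary.total_genomes if summary.total_genomes else 0.0
            ),
        }
        for region, count in sorted(summary.regions.items(), key=lambda kv: sorted(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "count", "pct_of_total"])


# ---------------------------------------------------------------------------
# Conditional co-occurrence


def _eval_expr(expr: FlagExpr, row: Mapping[str, bool]) -> bool:
    if callable(expr):
        return bool(expr(row))
    return bool(row[expr])


def cond_cooccurrence(profiles, given: FlagExpr, also: FlagExpr) -> float | None:
    """100 x |given AND also| / |given|, one-decimal half-up.

    Returns None (undefined, not 0) when no genome satisfies ``given``.
    ``given``/``also`` are flag names or predicates over the flag row.
    """
    frame = _as_frame(profiles)
    n_given = 0
    n_both = 0
    for _, row in frame.iterrows():
        if _eval_expr(given, row):
            n_given += 1
            if _eval_expr(also, row):
                n_both += 1
    if n_given == 0:
        return None
    return round_half_up(100.0 * n_both / n_given, 1)


# ---------------------------------------------------------------------------
# Per-phylum normalized distribution


@dataclass
class TaxonSummary:
    phylum: str
    genomes_in_phylum: int
    percentages: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def phylum_table(profiles, features: Sequence[str]) -> list[TaxonSummary]:
    """Per-phylum feature percentages, normalized to phylum size (never pooled)."""
    frame = _as_frame(profiles)
    unknown = [f for f in features if f not in frame.columns]
    if unknown:
        raise KeyError(f"unknown flag name(s): {unknown}")
    out: list[TaxonSummary] = []
    for phylum, sub in frame.groupby("phylum", sort=True):
        n = len(sub)
        counts = {f: int(sub[f].astype(bool).sum()) for f in features}
        out.append(
            TaxonSummary(
                phylum=str(phylum),
                genomes_in_phylum=n,
                percentages={f: round_half_up(100.0 * c / n, 1) for f, c in counts.items()},
                counts=counts,
            )
        )
    return out


def phylum_table_to_frame(summaries: Sequence[TaxonSummary]) -> pd.DataFrame:
    rows = [
        {
            "phylum": s.phylum,
            "genomes_in_phylum": s.genomes_in_phylum,
            "feature": f,
            "count": s.counts[f],
            "percentage": s.percentages[f],
        }
        for s in summaries
        for f in s.percentages
    ]
    return pd.DataFrame(
        rows, columns=["phylum", "genomes_in_phylum", "feature", "count", "percentage"]
    )


# ---------------------------------------------------------------------------
# Canned co-occurrence report


def cooccurrence_report(profiles) -> dict[str, float | None]:
    """The headline conditional co-occurrence values for one domain's matrix.

    Keys name the conditional: e.g. ``lipT_given_lipS1S2`` is the
    percentage of LipS1/S2-containing genomes that also encode LipT.
    """
    frame = _as_frame(profiles)
    both = lambda row: row["Lpl"] and row["LipA"]  # noqa: E731
    return {
        "lpl_and_lipA_pct": cond_cooccurrence(frame, lambda r: True, both),
        "lpl_and_lipS1S2_pct": cond_cooccurrence(
            frame, lambda r: True, lambda r: r["Lpl"] and r["LipS1S2"]
        ),
        "lipS1S2_given_lipT": cond_cooccurrence(frame, "LipT", "LipS1S2"),
        "lipT_given_lipS1S2": cond_cooccurrence(frame, "LipS1S2", "LipT"),
        "lipS1S2_given_sHdr": cond_cooccurrence(frame, "sHdr", "LipS1S2"),
        "sHdr_given_lipS1S2": cond_cooccurrence(frame, "LipS1S2", "sHdr"),
    }
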