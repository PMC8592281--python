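"""Reading, validating and writing GWAS summary statistics and auxiliary tables.

Summary statistics are the universal currency of the pipeline: one table per
trait with one row per biallelic SNV carrying the per-allele effect estimate,
its standard error, the association p-value and (optionally) the effect-allele
frequency and sample size.  Files are plain TSV with a header; a ``column_map``
translates arbitrary source headers onto the canonical names, because every
GWAS consortium ships its own layout.

Rows violating the per-record invariants (non-ACGT or identical alleles,
non-positive SE, p outside (0, 1], frequency outside [0, 1]) are dropped on
read and counted, never silently kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of a summary-statistics table
SUMSTATS_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

REQUIRED_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]

TRAIT_KINDS = ("food_item", "pc_trait", "confounder", "metabolite")


class ConfigError(ValueError):
    """A configuration problem (missing column, bad threshold, absent file)."""


class InputError(ValueError):
    """Input data that cannot be used (zero valid rows, malformed matrix)."""


@dataclass
class SumStats:
    """One trait's GWAS summary statistics.

    ``df`` is indexed by ``snp_id`` and carries the canonical columns
    (minus snp_id).  ``eaf`` and ``n`` may hold NaN where the source file
    omitted them.
    """

    trait_name: str
    df: pd.DataFrame
    trait_kind: str = "food_item"

    def __post_init__(self) -> None:
        if self.trait_kind not in TRAIT_KINDS:
            raise ConfigError(f"unknown trait_kind {self.trait_kind!r}")
        if self.df.index.has_duplicates:
            raise InputError(f"{self.trait_name}: duplicate snp_id in summary statistics")
        if len(self.df) == 0:
            raise InputError(f"{self.trait_name}: empty summary statistics")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Index:
        return self.df.index

    def pvalues(self) -> pd.Series:
        return self.df["pvalue"]

    # -- cached array views (the pipeline touches thousands of pairs; going
    #    through DataFrame.loc per pair is an order of magnitude slower) ---

    def positions(self) -> dict:
        """snp_id -> integer row position (cached; df must not mutate)."""
        cache = self.__dict__.get("_positions")
        if cache is None:
            cache = {s: i for i, s in enumerate(self.df.index)}
            self.__dict__["_positions"] = cache
        return cache

    def column(self, name: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_colcache", {})
        if name not in cache:
            cache[name] = self.df[name].to_numpy()
        return cache[name]


def _validate_frame(df: pd.DataFrame, trait_name: str) -> pd.DataFrame:
    """Drop rows violating SnpRecord invariants; log a count per reason."""
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    reasons = {
        "bad_allele": ~(
            df["effect_allele"].isin(VALID_ALLELES)
            & df["other_allele"].isin(VALID_ALLELES)
        ),
        "same_alleles": df["effect_allele"] == df["other_allele"],
        "bad_se": ~(pd.to_numeric(df["se"], errors="coerce") > 0),
        "bad_pvalue": ~(
            (pd.to_numeric(df["pvalue"], errors="coerce") > 0)
            & (pd.to_numeric(df["pvalue"], errors="coerce") <= 1)
        ),
        "bad_beta": ~np.isfinite(pd.to_numeric(df["beta"], errors="coerce")),
    }
    if "eaf" in df:
        eaf = pd.to_numeric(df["eaf"], errors="coerce")
        reasons["bad_eaf"] = df["eaf"].notna() & ~((eaf >= 0) & (eaf <= 1))
    if "n" in df:
        n = pd.to_numeric(df["n"], errors="coerce")
        reasons["bad_n"] = df["n"].notna() & ~(n > 0)

    bad = pd.Series(False, index=df.index)
    for reason, mask in reasons.items():
        mask = mask.fillna(False) if mask.dtype == object else mask
        n_bad = int((mask & ~bad).sum())
        if n_bad:
            logger.warning("%s: dropped %d row(s): %s", trait_name, n_bad, reason)
        bad |= mask
    return df.loc[~bad]


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_kind: str = "food_item",
) -> SumStats:
    """Read one trait's summary statistics from a delimited table.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Maps canonical names (``snp_id``, ``effect_allele``, ...) to the
        column headers used in the file.  Unmapped canonical names are
        assumed to appear verbatim.
    trait_name
        Defaults to the file stem.

    Raises
    ------
    ConfigError
        if a required column cannot be resolved.
    InputError
        if no row survives validation.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    column_map = dict(column_map or {})
    rename = {}
    for canonical in SUMSTATS_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise ConfigError(f"{path}: required column {canonical!r} "
                              f"(source header {source!r}) not found")
    df = raw.rename(columns=rename)
    for optional in ("eaf", "n"):
        if optional not in df:
            df[optional] = np.nan
    df = df[SUMSTATS_COLUMNS]
    df["snp_id"] = df["snp_id"].astype(str)
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    df = _validate_frame(df, trait_name or path.stem)
    if len(df) == 0:
        raise InputError(f"{path}: zero valid rows after validation")
    return SumStats(
        trait_name=trait_name or path.stem,
        df=df.set_index("snp_id"),
        trait_kind=trait_kind,
    )


def write_sumstats(stats: SumStats, path: str | Path) -> None:
    """Write a SumStats back to canonical TSV."""
    out = stats.df.reset_index()[SUMSTATS_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class LdTable:
    """Pairwise linkage-disequilibrium r² lookups.

    Stored sparsely: an absent pair means r² = 0 (the SNPs are treated as
    independent).  Keys are unordered pairs.
    """

    pairs: dict[frozenset, float] = field(default_factory=dict)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(frozenset((a, b)), 0.0)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise InputError(f"r2 out of range for ({a}, {b}): {r2}")
        if a != b:
            self.pairs[frozenset((a, b))] = float(r2)

    def neighbors(self, a: str) -> dict[str, float]:
        out = {}
        for pair, r2 in self.pairs.items():
            if a in pair:
                (other,) = pair - {a}
                out[other] = r2
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def read_ld_table(path: str | Path) -> LdTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    table = LdTable()
    for row in df.itertuples(index=False):
        table.set(str(row.snp_a), str(row.snp_b), float(row.r2))
    return table


def write_ld_table(table: LdTable, path: str | Path) -> None:
    rows = [
        {"snp_a": a, "snp_b": b, "r2": r2}
        for pair, r2 in sorted(table.pairs.items(), key=lambda kv: sorted(kv[0]))
        for a, b in [sorted(pair)]
    ]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


@dataclass
class GroupSpec:
    """A dietary-pattern (PC) trait definition.

    ``member_items`` are the food items (or previously defined PC traits,
    for hierarchical patterns) whose genetic correlation matrix is
    decomposed; ``pc_index`` selects which principal component (1-based)
    this trait is.
    """

    group_name: str
    member_items: list[str]
    pc_index: int

    def __post_init__(self) -> None:
        if len(self.member_items) < 2:
            raise ConfigError(f"{self.group_name}: a PC group needs >= 2 members")
        if len(set(self.member_items)) != len(self.member_items):
            raise ConfigError(f"{self.group_name}: duplicate member items")
        if not 1 <= self.pc_index <= len(self.member_items):
            raise ConfigError(
                f"{self.group_name}: pc_index {self.pc_index} outside "
                f"1..{len(self.member_items)}"
            )


def read_groups_yaml(path: str | Path) -> list[GroupSpec]:
    """Load GroupSpecs from YAML: a list of {group_name, member_items, pc_index}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        GroupSpec(
            group_name=entry["group_name"],
            member_items=list(entry["member_items"]),
            pc_index=int(entry.get("pc_index", 1)),
        )
        for entry in raw
    ]


def write_groups_yaml(groups: Sequence[GroupSpec], path: str | Path) -> None:
    payload = [
        {
            "group_name": g.group_name,
            "member_items": list(g.member_items),
            "pc_index": g.pc_index,
        }
        for g in groups
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_correlation_matrix(path: str | Path) -> pd.DataFrame:
    """Read a symmetric trait-by-trait correlation matrix from TSV.

    First column holds trait names; the header row repeats them.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InputError(f"{path}: row and column trait names differ")
    return df.astype(float)


def write_correlation_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", float_format="%.12g")


RESULTS_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "nsnp",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "qvalue",
    "Q",
    "Q_pvalue",
    "model",
]


def results_to_frame(results: Iterable, qvalues: Mapping | None = None) -> pd.DataFrame:
    """Flatten MrResult objects into the canonical results table."""
    qvalues = qvalues or {}
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "method": r.method,
                "nsnp": r.nsnp,
                "beta": r.beta,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pvalue": r.pvalue,
                "qvalue": qvalues.get((r.exposure, r.outcome, r.method), np.nan),
                "Q": r.Q if r.Q is not None else np.nan,
                "Q_pvalue": r.Q_pvalue if r.Q_pvalue is not None else np.nan,
                "model": r.variance_model,
            }
        )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def write_results_table(results, path: str | Path, qvalues: Mapping | None = None) -> None:
    """Write MR results as TSV; numerics round-trip to 12 significant digits."""
    results = list(results)
    if not results:
        raise InputError("write_results_table: empty result collection")
    results_to_frame(results, qvalues).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
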