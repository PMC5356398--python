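"""Expression-matrix container and preprocessing for multi-genotype time series.

The central object is :class:`ExpressionMatrix`: a log2-scale gene x sample
table whose sample keys encode genotype, time and (optionally) replicate as
``<genotype>:<time>:<replicate>`` (or ``<genotype>:<time>`` after replicate
averaging).  Downstream stages expect the matrix in the "combined" layout:
replicate-averaged, fold-change filtered, with columns grouped per genotype in
time order, so that l genotypes x m time points give M = l*m columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionFormatError(ValueError):
    """Malformed expression table (header, duplicate key or non-numeric cell)."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values with genotype/time/replicate sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        genes x samples, index = gene ids, columns = sample keys.
    samples : pandas.DataFrame
        One row per sample key with columns ``genotype`` (str), ``time``
        (float) and ``replicate`` (nullable int; absent after averaging).
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = parse_sample_keys(list(self.values.columns))
        if len(self.values.columns) != len(self.samples):
            raise ExpressionFormatError("values/samples column mismatch")
        if self.values.index.has_duplicates:
            raise ExpressionFormatError("duplicate gene ids")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ExpressionFormatError(f"duplicate sample key {dup!r}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ExpressionFormatError("non-finite expression value")
        if self.values.shape[0] == 0:
            raise ExpressionFormatError("empty expression matrix")

    # -- basic introspection -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.samples["genotype"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def times(self) -> list[float]:
        return sorted(set(self.samples["time"]))

    @property
    def has_replicates(self) -> bool:
        return "replicate" in self.samples.columns and self.samples["replicate"].notna().any()

    def columns_for(self, genotype: str, time: float | None = None) -> list[str]:
        m = self.samples["genotype"] == genotype
        if time is not None:
            m &= self.samples["time"] == time
        return list(self.samples.index[m])

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy())


def parse_sample_keys(keys: list[str]) -> pd.DataFrame:
    """Parse ``genotype:time[:replicate]`` sample keys into a metadata frame."""
    rows = []
    for key in keys:
        parts = str(key).split(":")
        if len(parts) not in (2, 3):
            raise ExpressionFormatError(
                f"sample key {key!r} is not '<genotype>:<time>[:<replicate>]'"
            )
        try:
            time = float(parts[1])
        except ValueError as exc:
            raise ExpressionFormatError(f"non-numeric time in sample key {key!r}") from exc
        rep: float | None = None
        if len(parts) == 3:
            try:
                rep = int(parts[2])
            except ValueError as exc:
                raise ExpressionFormatError(
                    f"non-integer replicate in sample key {key!r}"
                ) from exc
        rows.append((key, parts[0], time, rep))
    df = pd.DataFrame(rows, columns=["key", "genotype", "time", "replicate"]).set_index("key")
    return df


def read_expression(path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, headers = sample keys)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ExpressionFormatError(f"non-numeric cell in {path}: {exc}") from exc
    # pandas mangles duplicate headers; detect them from the raw header line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ExpressionFormatError(f"duplicate sample key {dup!r} in {path}")
    values.columns = header
    return ExpressionMatrix(values)


def average_replicates(x: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns, yielding one profile per (genotype, time).

    The replicate index is dropped from the sample keys; the output has
    l*m columns ordered genotype-block by ascending time.
    """
    if not x.has_replicates:
        return x.copy()
    meta = x.samples
    groups: dict[tuple[str, float], list[str]] = {}
    for key, row in meta.iterrows():
        groups.setdefault((row["genotype"], row["time"]), []).append(key)
    genotypes = x.genotypes
    times = x.times
    missing = [
        (g, t) for g in genotypes for t in times if (g, t) not in groups
    ]
    if missing:
        raise ValueError(f"missing (genotype, time) combinations: {missing}")
    cols, data = [], []
    for g in genotypes:
        for t in times:
            cols.append(f"{g}:{t:g}")
            data.append(x.values[groups[(g, t)]].mean(axis=1))
    values = pd.concat(data, axis=1)
    values.columns = cols
    return ExpressionMatrix(values)


def fold_change_filter(
    x: ExpressionMatrix,
    min_log2_range: float = 1.0,
    scope: str = "any",
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose temporal range is below a fold-change cutoff.

    A gene is kept iff max - min of its log2 profile over the time course is
    >= ``min_log2_range`` (inclusive, so the default 1.0 keeps genes changing
    by at least 2-fold).  With ``scope="any"`` (default) the range must be
    reached in at least one genotype; with ``scope="per-genotype"`` in every
    genotype.  Expects replicate-averaged input.

    Returns the filtered matrix and the list of dropped gene ids.
    """
    if min_log2_range < 0:
        raise ValueError("min_log2_range must be non-negative")
    if scope not in ("any", "per-genotype"):
        raise ValueError(f"unknown scope {scope!r}")
    ranges = []
    for g in x.genotypes:
        block = x.values[x.columns_for(g)]
        ranges.append(block.max(axis=1) - block.min(axis=1))
    per_geno = pd.concat(ranges, axis=1)
    if scope == "any":
        keep = (per_geno >= min_log2_range).any(axis=1)
    else:
        keep = (per_geno >= min_log2_range).all(axis=1)
    dropped = [g for g, k in keep.items() if not k]
    kept = x.values.loc[keep]
    if kept.shape[0] == 0:
        raise ValueError("fold-change filter dropped every gene")
    return ExpressionMatrix(kept, x.samples.copy()), dropped


def combine_genotypes(
    x: ExpressionMatrix, genotype_order: list[str] | None = None
) -> ExpressionMatrix:
    """Order columns as per-genotype time-series blocks (the combined A matrix).

    All genotypes must share the same time grid; the output has M = l*m
    columns, the concatenation of each genotype's series in ``genotype_order``.
    """
    if x.has_replicates:
        raise ValueError("combine_genotypes expects replicate-averaged input")
    order = genotype_order if genotype_order is not None else x.genotypes
    grids = {g: sorted(x.samples.loc[x.columns_for(g), "time"]) for g in order}
    ref = grids[order[0]]
    for g, grid in grids.items():
        if grid != ref:
            raise ValueError(f"genotype {g!r} time grid {grid} != {ref}")
    cols: list[str] = []
    for g in order:
        block = x.samples.loc[x.columns_for(g)].sort_values("time")
        cols.extend(block.index)
    return ExpressionMatrix(x.values[cols], x.samples.loc[cols])


def anova_gxt(x: ExpressionMatrix) -> pd.DataFrame:
    """Gene-wise two-way fixed-effects ANOVA with interaction.

    Fits y = mu + genotype + time + genotype x time + error per gene on the
    replicated matrix, using the balanced-design sum-of-squares decomposition
    (all genes share the design, so the partition is fully vectorized).

    Returns a DataFrame indexed by gene with SS, F and p-value columns for the
    genotype, time and interaction effects plus the residual df.
    """
    if not x.has_replicates:
        raise ValueError("anova_gxt needs replicated data")
    genotypes, times = x.genotypes, x.times
    l, m = len(genotypes), len(times)
    if l < 2 or m < 2:
        raise ValueError("need >=2 genotypes and >=2 time points")
    cells: dict[tuple[str, float], list[str]] = {}
    for key, row in x.samples.iterrows():
        cells.setdefault((row["genotype"], row["time"]), []).append(key)
    counts = {c: len(k) for c, k in cells.items()}
    r = min(counts.values(), default=0)
    if r < 2:
        bad = min(counts, key=counts.get) if counts else ("?", "?")
        raise ValueError(f"insufficient replication in cell {bad}")
    if len(set(counts.values())) != 1 or len(counts) != l * m:
        raise ValueError("anova_gxt requires a balanced complete design")

    vals = x.values.to_numpy(dtype=float)
    n_genes = vals.shape[0]
    # reshape to genes x l x m x r following the cell layout
    y = np.empty((n_genes, l, m, r))
    for i, g in enumerate(genotypes):
        for j, t in enumerate(times):
            y[:, i, j, :] = vals[:, [x.values.columns.get_loc(k) for k in cells[(g, t)]]]

    grand = y.mean(axis=(1, 2, 3))
    mean_g = y.mean(axis=(2, 3))            # genes x l
    mean_t = y.mean(axis=(1, 3))            # genes x m
    mean_gt = y.mean(axis=3)                # genes x l x m

    ss_g = m * r * ((mean_g - grand[:, None]) ** 2).sum(axis=1)
    ss_t = l * r * ((mean_t - grand[:, None]) ** 2).sum(axis=1)
    ss_gt = r * (
        (mean_gt - mean_g[:, :, None] - mean_t[:, None, :] + grand[:, None, None]) ** 2
    ).sum(axis=(1, 2))
    ss_e = ((y - mean_gt[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))

    df_g, df_t = l - 1, m - 1
    df_gt = df_g * df_t
    df_e = l * m * (r - 1)
    mse = ss_e / df_e

    def f_and_p(ss, df):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / mse
        f = np.where(mse > 0, f, np.where(ss > 0, np.inf, 0.0))
        return f, stats.f.sf(f, df, df_e)

    f_g, p_g = f_and_p(ss_g, df_g)
    f_t, p_t = f_and_p(ss_t, df_t)
    f_gt, p_gt = f_and_p(ss_gt, df_gt)

    return pd.DataFrame(
        {
            "ss_genotype": ss_g, "F_genotype": f_g, "p_genotype": p_g,
            "ss_time": ss_t, "F_time": f_t, "p_time": p_t,
            "ss_interaction": ss_gt, "F_interaction": f_gt, "p_interaction": p_gt,
            "ss_residual": ss_e, "df_residual": df_e,
        },
        index=x.values.index,
    )
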