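"""Relative quantification of qPCR data by the relative standard curve method.

For each gene a serial-dilution standard series gives the least-squares line
CT = intercept + slope * log10(quantity), with amplification efficiency
E = 10^(-1/slope). Unknown CTs are mapped back to quantities through the
gene's own curve (so no E = 2 assumption is needed), technical replicates are
averaged on the CT scale first, and each sample's target quantity is
normalized by the geometric mean of its reference-gene quantities (Elongation
Factor 1 and Ubiquitin in the original assay; any reference set works).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError

WELL_COLUMNS = (
    "gene", "sample_id", "biological_replicate", "technical_replicate",
    "ct", "role", "standard_quantity",
)


@dataclass
class StandardCurve:
    """Per-gene dilution-series regression of CT on log10(quantity)."""

    gene: str
    slope: float       # cycles per log10(quantity); negative
    intercept: float   # cycles at quantity 1
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Least-squares standard curve from the standard wells of one gene.

    Needs at least 3 distinct dilution quantities; the fitted slope must be
    negative (more template, earlier CT).
    """
    if standards.empty:
        raise AnalysisError("no standard wells supplied")
    genes = standards["gene"].unique()
    if len(genes) != 1:
        raise AnalysisError(f"standard wells span several genes: {sorted(genes)}")
    gene = str(genes[0])
    q = standards["standard_quantity"].to_numpy(dtype=float)
    ct = standards["ct"].to_numpy(dtype=float)
    if (q <= 0).any():
        raise AnalysisError(f"{gene}: standard quantities must be > 0")
    if len(np.unique(q)) < 3:
        raise AnalysisError(
            f"{gene}: at least 3 distinct dilution points are required, got {len(np.unique(q))}"
        )
    fit = stats.linregress(np.log10(q), ct)
    if not (fit.slope < 0):
        raise AnalysisError(
            f"{gene}: standard-curve slope must be negative, got {fit.slope:.4g}"
        )
    return StandardCurve(
        gene=gene, slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
    )


def relative_quantity(ct, curve: StandardCurve):
    """Quantity (arbitrary units) for a CT value under a fitted curve.

    quantity = 10^((ct - intercept) / slope); monotone decreasing in ct.
    Accepts scalars or arrays.
    """
    return 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)


def normalize_expression(
    target: pd.Series, references: pd.DataFrame, combine: str = "geomean"
) -> pd.Series:
    """Normalize per-sample target quantities by the reference-gene factor.

    ``target`` is indexed by sample, ``references`` has one column per
    reference gene on the same index. The normalization factor is the
    geometric mean of the reference quantities (arithmetic mean with
    ``combine="mean"``).
    """
    if combine not in ("geomean", "mean"):
        raise ConfigurationError(f"combine must be 'geomean' or 'mean', got {combine!r}")
    missing = references.isna().any(axis=1)
    if missing.any():
        raise AnalysisError(
            f"missing reference quantity for sample(s): {list(references.index[missing])}"
        )
    if combine == "geomean":
        factor = np.exp(np.log(references).mean(axis=1))
    else:
        factor = references.mean(axis=1)
    return target / factor


def quantify(
    wells: pd.DataFrame,
    ref_genes=("EF1", "UBQ"),
    combine: str = "geomean",
) -> tuple[dict[str, StandardCurve], pd.DataFrame]:
    """Full relative quantification of a well table.

    Steps: fit one standard curve per gene; average technical replicates on
    the CT scale per (gene, sample, biological replicate); convert mean CTs to
    quantities via the gene's curve; normalize each sample unit by its
    reference-gene factor. Returns the curves and a tidy table with columns
    gene, sample_id, biological_replicate, mean_ct, quantity,
    normalized_expression.
    """
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise AnalysisError(f"well table lacks columns: {sorted(missing)}")
    ref_genes = tuple(ref_genes)
    present = set(wells["gene"])
    absent_refs = [g for g in ref_genes if g not in present]
    if absent_refs:
        raise AnalysisError(f"reference gene(s) not in well table: {absent_refs}")

    curves = {}
    for gene, grp in wells[wells["role"] == "standard"].groupby("gene"):
        curves[gene] = fit_standard_curve(grp)
    no_curve = sorted(present - set(curves))
    if no_curve:
        raise AnalysisError(f"gene(s) without standard wells: {no_curve}")

    unknowns = wells[wells["role"] == "unknown"]
    mean_ct = (
        unknowns.groupby(["gene", "sample_id", "biological_replicate"], observed=False)["ct"]
        .mean()
        .reset_index()
        .rename(columns={"ct": "mean_ct"})
    )
    mean_ct["quantity"] = [
        float(relative_quantity(row.mean_ct, curves[row.gene]))
        for row in mean_ct.itertuples()
    ]

    units = mean_ct.set_index(["sample_id", "biological_replicate"])
    ref_wide = (
        mean_ct[mean_ct["gene"].isin(ref_genes)]
        .pivot_table(
            index=["sample_id", "biological_replicate"], columns="gene",
            values="quantity",
        )
        .reindex(columns=list(ref_genes))
    )
    all_units = units.index.unique()
    ref_wide = ref_wide.reindex(all_units)

    out = mean_ct.copy()
    refs_for_rows = ref_wide.loc[
        pd.MultiIndex.from_frame(out[["sample_id", "biological_replicate"]])
    ]
    refs_for_rows.index = out.index
    out["normalized_expression"] = normalize_expression(
        out["quantity"], refs_for_rows, combine=combine
    ).to_numpy()
    return curves, out


def condition_ratio(
    quantified: pd.DataFrame,
    gene: str,
    numerator: str = "treated",
    denominator: str = "control",
) -> float:
    """Fold change between two conditions for one gene.

    Ratio of geometric means of the normalized expression over biological
    replicates (the geometric mean matches the log-scale error structure of
    CT measurements).
    """
    sub = quantified[quantified["gene"] == gene]
    num = sub.loc[sub["sample_id"] == numerator, "normalized_expression"]
    den = sub.loc[sub["sample_id"] == denominator, "normalized_expression"]
    if num.empty or den.empty:
        raise AnalysisError(f"missing condition data for gene {gene!r}")
    return float(math.exp(np.log(num).mean() - np.log(den).mean()))


def curves_frame(curves: dict[str, StandardCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene, "slope": c.slope, "intercept": c.intercept,
                "efficiency": c.efficiency, "r_squared": c.r_squared,
            }
            for c in curves.values()
        ]
    )
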