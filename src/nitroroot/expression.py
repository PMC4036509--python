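"""Expression-matrix container, TSV IO and the expressed-signal filter.

The matrix holds already-normalized log2 intensities (probes x samples) together
with a balanced two-genotype x two-nitrate factorial sample design. Probe-level
normalization happens upstream; this module only validates, filters and
round-trips the normalized matrix.

TSV dialect: tab separator, UTF-8, '.' decimal, no quoting. Floats are written
with ``repr`` precision so that read(write(m)) reproduces the values bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError

GENOTYPES = ("WT", "MUT")
NITRATES = ("HN", "LN")

METADATA_COLUMNS = ("sample_id", "genotype", "nitrate", "replicate")


def validate_design(design: pd.DataFrame) -> None:
    """Check a sample-design table (indexed by sample_id).

    Requires columns genotype/nitrate/replicate, known factor levels and
    unique (genotype, nitrate, replicate) triples.
    """
    missing = {"genotype", "nitrate", "replicate"} - set(design.columns)
    if missing:
        raise DesignError(f"design table lacks columns: {sorted(missing)}")
    if design.index.duplicated().any():
        dup = design.index[design.index.duplicated()][0]
        raise DesignError(f"duplicate sample id in design: {dup!r}")
    bad_g = set(design["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise DesignError(f"unknown genotype level(s) {sorted(bad_g)}; expected {GENOTYPES}")
    bad_n = set(design["nitrate"]) - set(NITRATES)
    if bad_n:
        raise DesignError(f"unknown nitrate level(s) {sorted(bad_n)}; expected {NITRATES}")
    reps = pd.to_numeric(design["replicate"], errors="coerce")
    if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
        raise DesignError("replicate must be a positive integer for every sample")
    triples = design[["genotype", "nitrate", "replicate"]]
    if triples.duplicated().any():
        t = triples[triples.duplicated()].iloc[0]
        raise DesignError(
            f"duplicate (genotype, nitrate, replicate) triple: "
            f"({t['genotype']}, {t['nitrate']}, {t['replicate']})"
        )


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities plus the factorial sample design.

    ``values``: DataFrame indexed by probe id, columns are sample ids.
    ``design``: DataFrame indexed by sample id with columns genotype, nitrate,
    replicate. Every sample column must appear in the design.
    """

    values: pd.DataFrame
    design: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate probe id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        validate_design(self.design)
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise DesignError(f"samples missing from metadata: {missing}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            raise ParseError("expression values must be finite")

    # -- basic accessors ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def balanced(self) -> bool:
        """True when all four genotype x nitrate cells have equal sample counts."""
        d = self.design.loc[self.sample_ids]
        counts = d.groupby(["genotype", "nitrate"], observed=False).size()
        if len(counts) != 4:
            return False
        return counts.nunique() == 1

    def replicates_per_cell(self) -> int:
        if not self.balanced():
            raise DesignError("design is not a balanced 2x2 factorial")
        return self.n_samples // 4

    def cell_array(self) -> np.ndarray:
        """Values reshaped to (n_genes, 2 genotypes, 2 nitrates, r replicates).

        Axis order follows GENOTYPES and NITRATES; replicates are ordered by
        their replicate label within each cell.
        """
        r = self.replicates_per_cell()
        d = self.design.loc[self.sample_ids]
        out = np.empty((self.n_genes, 2, 2, r), dtype=float)
        for i, g in enumerate(GENOTYPES):
            for j, n in enumerate(NITRATES):
                cell = d[(d["genotype"] == g) & (d["nitrate"] == n)]
                cell = cell.sort_values("replicate")
                out[:, i, j, :] = self.values[cell.index].to_numpy()
        return out


def read_expression_matrix(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a probes x samples TSV and its sample-metadata TSV.

    The matrix file has a header row of sample ids and probe ids in the first
    column. The metadata file has columns sample_id, genotype, nitrate,
    replicate. Row and column order are preserved from the files.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{matrix_path}: duplicate probe id {dup!r}")
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            # numpy's text-to-float64 conversion is exact (unlike pandas'
            # fast parser), which the bit-exact round-trip relies on
            values[col] = raw[col].to_numpy().astype(np.float64)
        except ValueError:
            for pos, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except ValueError:
                    # +2: one for the header row, one for 1-based line numbers
                    raise ParseError(
                        f"{matrix_path}: non-numeric value {cell!r} at line "
                        f"{pos + 2}, column {col!r} (probe {raw.index[pos]!r})"
                    ) from None
            raise

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ParseError(f"{metadata_path}: missing column(s) {sorted(missing_cols)}")
    design = meta.set_index("sample_id")
    absent = [s for s in values.columns if s not in design.index]
    if absent:
        raise ParseError(f"{metadata_path}: no metadata for sample(s) {absent}")
    try:
        return ExpressionMatrix(values=values, design=design)
    except DesignError as exc:
        raise ParseError(f"{metadata_path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    """Write matrix + metadata as the package's TSV dialect (round-trip exact)."""
    vals = matrix.values.copy()
    vals.index.name = "probe_id"
    # 17 significant digits round-trip any float64 bit-exactly through text
    vals.to_csv(matrix_path, sep="\t", float_format="%.17g")
    meta = matrix.design.loc[matrix.sample_ids].reset_index()
    meta.columns = ["sample_id", *matrix.design.columns]
    meta.to_csv(metadata_path, sep="\t", index=False)


def filter_expressed(
    matrix: ExpressionMatrix, threshold: float = 4.0
) -> tuple[ExpressionMatrix, int]:
    """Keep probes whose maximum log2 signal over all samples exceeds ``threshold``.

    The comparison is strict (> threshold), so probes tied exactly at the
    threshold are removed. Probe order is preserved. Returns the filtered
    matrix and the number of probes removed.
    """
    if matrix.n_genes == 0:
        return matrix, 0
    keep = matrix.values.max(axis=1) > threshold
    filtered = ExpressionMatrix(values=matrix.values.loc[keep], design=matrix.design)
    return filtered, int((~keep).sum())
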