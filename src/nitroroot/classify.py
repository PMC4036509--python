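"""Differential-expression classification: declared sets, Venn partition,
effect direction/magnitude and overlaps with external regulated-gene lists.

A gene is declared responsive to a contrast when its Bonferroni-adjusted
p-value is strictly below alpha. The three declared sets (genotype G, nitrate
N, interaction GxN) overlap; both the overlapping totals (the counts a Venn
diagram prints per circle) and the seven disjoint cells are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .anova import ContrastTable, GeneAnovaFit
from .errors import AnalysisError, ConfigurationError

VENN_CELLS = ("G_only", "N_only", "GxN_only", "G_N", "G_GxN", "N_GxN", "G_N_GxN")


@dataclass
class DEClassification:
    """Per-gene declared flags at level alpha plus the Venn partition."""

    flags: pd.DataFrame  # columns: probe_id, declared_G, declared_N, declared_GxN
    alpha: float
    totals: dict[str, int] = field(default_factory=dict)       # per-contrast totals + union
    venn_cells: dict[str, int] = field(default_factory=dict)   # 7 disjoint cells

    def declared_ids(self, contrast: str | None = None) -> set[str]:
        """Ids declared for one contrast, or for the union when contrast is None."""
        f = self.flags
        if contrast is None:
            mask = f[["declared_G", "declared_N", "declared_GxN"]].any(axis=1)
        else:
            mask = f[f"declared_{contrast}"]
        return set(f.loc[mask, "probe_id"])


@dataclass
class OverlapReport:
    """Intersection sizes between a declared set and named external lists."""

    declared_size: int
    per_list: dict[str, int]
    multi: dict[str, int]  # "+"-joined sorted list names -> co-membership count


def classify_de(table: ContrastTable, alpha: float = 0.05) -> DEClassification:
    """Declare genes per contrast at adjusted p < alpha and partition the union.

    The inequality is strict: a gene with adjusted p exactly equal to alpha is
    not declared.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    for c in ("G", "N", "GxN"):
        if f"padj_{c}" not in table.data.columns:
            raise AnalysisError("adjusted p-values not present; run adjust_bonferroni first")
    flags = pd.DataFrame(
        {
            "probe_id": table.data["probe_id"],
            "declared_G": table.data["padj_G"] < alpha,
            "declared_N": table.data["padj_N"] < alpha,
            "declared_GxN": table.data["padj_GxN"] < alpha,
        }
    )
    g = flags["declared_G"].to_numpy()
    n = flags["declared_N"].to_numpy()
    i = flags["declared_GxN"].to_numpy()
    venn = {
        "G_only": int((g & ~n & ~i).sum()),
        "N_only": int((~g & n & ~i).sum()),
        "GxN_only": int((~g & ~n & i).sum()),
        "G_N": int((g & n & ~i).sum()),
        "G_GxN": int((g & ~n & i).sum()),
        "N_GxN": int((~g & n & i).sum()),
        "G_N_GxN": int((g & n & i).sum()),
    }
    totals = {
        "G": int(g.sum()),
        "N": int(n.sum()),
        "GxN": int(i.sum()),
        "union": int((g | n | i).sum()),
    }
    return DEClassification(flags=flags, alpha=alpha, totals=totals, venn_cells=venn)


def effect_direction(
    fit: GeneAnovaFit, contrast: str, magnitude_threshold: float = 1.0
) -> dict:
    """Direction and magnitude call for a main-effect contrast.

    For G the signed difference is (MUT marginal mean - WT marginal mean),
    for N it is (LN - HN). ``strong`` flags |difference| strictly above the
    log2 magnitude threshold. A zero difference is reported as the "down"
    direction with ``tie = True`` so output stays deterministic. The
    interaction has no single direction; inspect the cell means instead.
    """
    if contrast == "G":
        diff = float(fit.genotype_means[1] - fit.genotype_means[0])
        up, down = "up_in_MUT", "down_in_MUT"
    elif contrast == "N":
        diff = float(fit.nitrate_means[1] - fit.nitrate_means[0])
        up, down = "up_in_LN", "down_in_LN"
    else:
        raise AnalysisError(
            "effect_direction is defined for the G and N contrasts only; "
            "the interaction is described by its four cell means"
        )
    return {
        "direction": up if diff > 0 else down,
        "difference": diff,
        "strong": abs(diff) > magnitude_threshold,
        "tie": diff == 0.0,
    }


def overlap_with_lists(declared_ids: set[str], lists: dict[str, set[str]]) -> OverlapReport:
    """Exact intersections of a declared set with named external gene lists.

    ``multi`` holds, for every combination of two or more lists, the number of
    declared ids belonging to all lists of the combination (key: sorted names
    joined by '+').
    """
    declared = set(declared_ids)
    per_list = {name: len(declared & set(ids)) for name, ids in lists.items()}
    multi: dict[str, int] = {}
    names = sorted(lists)
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter = declared.copy()
            for name in combo:
                inter &= set(lists[name])
            multi["+".join(combo)] = len(inter)
    return OverlapReport(declared_size=len(declared), per_list=per_list, multi=multi)


def read_gene_list(path) -> set[str]:
    """Read a one-id-per-line text file (blank lines and '#' comments ignored)."""
    ids = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids
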