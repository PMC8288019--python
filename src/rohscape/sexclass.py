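"""Sex-linked scaffold classification from female:male coverage ratios.

In a female/male pair sequenced to similar autosomal depth, the per-scaffold
female:male mean-coverage ratio separates into three groups: autosomes (~1),
X-linked scaffolds (~2, two copies vs one) and Y-linked scaffolds (~0).
Scaffolds are classified by closed ratio ranges and downstream analyses are
restricted to autosomal scaffolds above a length threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SexClassPolicy:
    """Closed ratio ranges for Y and X scaffolds; everything else is autosomal."""

    y_ratio_range: tuple[float, float] = (0.0, 0.04)
    x_ratio_range: tuple[float, float] = (1.5, 2.5)
    min_scaffold_len: int = 40_000

    def __post_init__(self) -> None:
        y0, y1 = self.y_ratio_range
        x0, x1 = self.x_ratio_range
        if not (y0 <= y1 and x0 <= x1):
            raise ValueError("ratio range bounds must be ordered")
        if y1 >= x0:
            raise ValueError("Y and X ratio ranges must be disjoint")


def coverage_ratio(female: pd.DataFrame, male: pd.DataFrame) -> pd.DataFrame:
    """Per-scaffold female:male mean-depth ratio.

    Both inputs need columns (scaffold, length, mean_depth) over the same
    scaffold set.  A male depth of 0 with nonzero female depth yields +inf
    (classified autosomal, with a warning); 0/0 yields NaN, also autosomal.
    """
    fset, mset = set(female["scaffold"]), set(male["scaffold"])
    if fset != mset:
        missing = sorted(fset.symmetric_difference(mset))
        raise ValueError(f"scaffold sets differ between individuals: {missing}")
    f = female.set_index("scaffold")
    m = male.set_index("scaffold")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f["mean_depth"] / m["mean_depth"]
    if np.isinf(ratio).any() or ratio.isna().any():
        warnings.warn("male mean depth 0 on some scaffolds; their ratio is "
                      "inf/NaN and they will be classified autosomal")
    out = pd.DataFrame({"scaffold": ratio.index,
                        "length": f["length"].to_numpy(),
                        "ratio": ratio.to_numpy()})
    return out.reset_index(drop=True)


def classify_scaffolds(ratios: pd.DataFrame,
                       policy: SexClassPolicy = SexClassPolicy()) -> pd.DataFrame:
    """Label each scaffold autosome / X / Y from its coverage ratio.

    Ranges are closed at both ends; scaffolds not longer than
    ``min_scaffold_len`` are flagged ``excluded`` (but still labelled).
    """
    r = ratios["ratio"].to_numpy()
    y0, y1 = policy.y_ratio_range
    x0, x1 = policy.x_ratio_range
    label = np.full(len(r), "autosome", dtype=object)
    finite = np.isfinite(r)
    label[finite & (r >= y0) & (r <= y1)] = "Y"
    label[finite & (r >= x0) & (r <= x1)] = "X"
    out = ratios.copy()
    out["label"] = label
    out["excluded"] = out["length"] <= policy.min_scaffold_len
    return out


def classify_scaffolds_multi(female: pd.DataFrame, males: list[pd.DataFrame],
                             policy: SexClassPolicy = SexClassPolicy()
                             ) -> pd.DataFrame:
    """Classification against several males, requiring unanimity.

    Each male yields its own female:male classification; scaffolds on which
    the males disagree fall back to autosome with a warning.
    """
    if not males:
        raise ValueError("at least one male required")
    per_male = [classify_scaffolds(coverage_ratio(female, m), policy)
                for m in males]
    base = per_male[0][["scaffold", "length", "excluded"]].copy()
    labels = np.stack([p["label"].to_numpy() for p in per_male])
    unanimous = (labels == labels[0]).all(axis=0)
    final = np.where(unanimous, labels[0], "autosome")
    if not unanimous.all():
        ties = base["scaffold"].to_numpy()[~unanimous]
        warnings.warn(f"non-unanimous sex classification for {list(ties)}; "
                      "labelled autosome")
    base["label"] = final
    base["ratio"] = np.mean(
        np.stack([p["ratio"].to_numpy() for p in per_male]), axis=0)
    return base


def autosomal_subset(labels: pd.DataFrame, scaffold_table: pd.DataFrame,
                     min_len: int = 40_000) -> tuple[pd.DataFrame, int]:
    """Autosome-labelled scaffolds strictly longer than ``min_len``.

    Returns the subset of the scaffold table and its summed length.  An
    empty result warns rather than fails.
    """
    auto = set(labels.loc[labels["label"] == "autosome", "scaffold"])
    sub = scaffold_table[scaffold_table["scaffold"].isin(auto)
                         & (scaffold_table["length"] > min_len)]
    sub = sub.reset_index(drop=True)
    total = int(sub["length"].sum())
    if len(sub) == 0:
        warnings.warn("no autosomal scaffolds pass the length threshold")
    return sub, total
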