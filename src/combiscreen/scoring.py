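"""Screen scoring: UMI filtering, normalization, activation and toxicity.

The activation score of a sufficiently covered UMI group is the dot product
of its normalized read profile over the four sort bins with the bins' mean
fluorescence intensities:

    score = sum_bin normalized_reads[bin] * MFI[bin]

so read mass in high-expression bins earns a higher score. A construct's
score is the mean over its UMI groups, then over replicates.

Toxicity compares a construct's abundance in unsorted transduced cells to
the plasmid pool:

    toxicity = -log2((reads_cells + 1) / (reads_plasmid + 1))

after pooling all UMIs and normalizing both conditions to a mean of 100
reads; one pseudoread guards against zeros. Higher values mean stronger
depletion from cells, i.e. more toxic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import BIN_CONDITIONS

_UNIT_KEYS = ["construct_id", "group", "condition", "replicate", "target"]


@dataclass
class FilterConfig:
    """Filtering and normalization parameters; all values are echoed into
    output metadata so no threshold is applied silently.

    umi_outlier_fraction: a UMI holding more than this share of its
    construct's reads within a condition is discarded (PCR jackpot guard).
    umi_prefix_length: 3 pools UMIs into 64 groups, 2 into 16, 0 aggregates
    all UMIs into one group per construct (used when coverage is low and
    always for toxicity).
    min_bin_sum: minimum summed normalized reads over the four bins for a
    group to be scored; the aggregated (prefix 0) default is set higher.
    """

    umi_outlier_fraction: float = 0.5
    umi_prefix_length: int = 3
    min_bin_sum: float = 10.0
    min_bin_sum_aggregated: float = 40.0
    normalization_target: float = 100.0
    pseudoread: float = 1.0
    negate_toxicity: bool = True  # higher score = more toxic

    def __post_init__(self) -> None:
        if not 0 < self.umi_outlier_fraction <= 1:
            raise ValueError("umi_outlier_fraction must be in (0, 1]")
        if self.umi_prefix_length not in (0, 2, 3):
            raise ValueError("umi_prefix_length must be 0, 2 or 3")
        if self.min_bin_sum < 0 or self.min_bin_sum_aggregated < 0:
            raise ValueError("min_bin_sum must be >= 0")
        if self.normalization_target <= 0:
            raise ValueError("normalization_target must be positive")

    @property
    def effective_min_bin_sum(self) -> float:
        if self.umi_prefix_length == 0:
            return self.min_bin_sum_aggregated
        return self.min_bin_sum

    def metadata(self) -> dict:
        return {
            "umi_outlier_fraction": self.umi_outlier_fraction,
            "umi_prefix_length": self.umi_prefix_length,
            "min_bin_sum": self.effective_min_bin_sum,
            "normalization_target": self.normalization_target,
            "pseudoread": self.pseudoread,
            "negate_toxicity": self.negate_toxicity,
        }


def filter_outlier_umis(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Drop UMIs dominating a construct's reads within any condition.

    A UMI is removed when its count strictly exceeds umi_outlier_fraction
    times its construct's total in that (condition, replicate, target) —
    the signature of PCR amplification bias or amplicon contamination.
    """
    if table.empty:
        return table.copy()
    keys = ["construct_id", "condition", "replicate", "target"]
    totals = table.groupby(keys)["count"].transform("sum")
    keep = table["count"] <= cfg.umi_outlier_fraction * totals
    return table.loc[keep].reset_index(drop=True)


def group_and_normalize(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Pool UMIs by prefix and rescale each condition to a common mean.

    Grouping by the first k UMI nucleotides yields 4**k groups per construct
    (64 for k=3, 16 for k=2; k=0 pools everything). Within each (condition,
    replicate, target) a single scalar rescales all group counts so their
    mean equals normalization_target, equalizing sequencing depth between
    conditions. Conditions with zero total reads are flagged and excluded.
    """
    k = cfg.umi_prefix_length
    df = table.copy()
    df["group"] = df["umi"].str[:k] if k > 0 else "all"
    grouped = (
        df.groupby(_UNIT_KEYS, sort=True)["count"].sum().rename("count").reset_index()
    )
    cond_keys = ["condition", "replicate", "target"]
    means = grouped.groupby(cond_keys)["count"].transform("mean")
    grouped["normalized"] = grouped["count"] * cfg.normalization_target / means
    grouped["flagged_zero_condition"] = ~np.isfinite(grouped["normalized"])
    grouped = grouped.loc[~grouped["flagged_zero_condition"]].drop(
        columns="flagged_zero_condition"
    )
    return grouped.reset_index(drop=True)


def activation_score(profile, mfi) -> float:
    """Eq.-style bin-weighted score: sum of normalized reads times bin MFI."""
    profile = np.asarray(profile, dtype=float)
    mfi = np.asarray(mfi, dtype=float)
    if profile.shape != (4,) or mfi.shape != (4,):
        raise ValueError("profile and MFI must have four bins")
    if (profile < 0).any():
        raise ValueError("normalized reads must be non-negative")
    if not (np.diff(mfi) > 0).all():
        raise ValueError("bin MFIs must be strictly increasing")
    return float(profile @ mfi)


def score_activation_screen(
    grouped: pd.DataFrame,
    mfi: pd.DataFrame,
    cfg: FilterConfig,
) -> pd.DataFrame:
    """Score every construct from grouped, normalized bin counts.

    Per (target, replicate): each surviving UMI group's four-bin profile is
    scored against that sort's MFI vector; groups whose summed normalized
    reads fall below the coverage threshold are excluded. A construct's
    replicate score is the mean over its groups; the final score the mean
    over replicates. Returns one row per (construct, target) with the score,
    the number of contributing groups, and n_replicates; constructs present
    in the input but never passing coverage appear with NaN score.
    """
    sorted_bins = grouped[grouped["condition"].isin(BIN_CONDITIONS)]
    wide = (
        sorted_bins.pivot_table(
            index=["construct_id", "group", "replicate", "target"],
            columns="condition",
            values="normalized",
            fill_value=0.0,
            aggfunc="sum",
        )
        .reindex(columns=BIN_CONDITIONS, fill_value=0.0)
        .reset_index()
    )
    profiles = wide[BIN_CONDITIONS].to_numpy(dtype=float)
    wide["bin_sum"] = profiles.sum(axis=1)

    mfi_lookup = {
        (t, r): sub.set_index("bin")["mfi"].reindex(BIN_CONDITIONS).to_numpy()
        for (t, r), sub in mfi.groupby(["target", "replicate"])
    }
    scores = np.full(len(wide), np.nan)
    for (t, r), idx in wide.groupby(["target", "replicate"]).indices.items():
        vec = mfi_lookup.get((t, r))
        if vec is None:
            raise ValueError(f"missing MFI vector for target={t} replicate={r}")
        if not (np.diff(vec) > 0).all():
            raise ValueError("bin MFIs must be strictly increasing")
        scores[idx] = profiles[idx] @ vec
    wide["score"] = scores

    covered = wide[wide["bin_sum"] >= cfg.effective_min_bin_sum]
    per_rep = (
        covered.groupby(["construct_id", "target", "replicate"])
        .agg(score=("score", "mean"), n_groups=("score", "size"))
        .reset_index()
    )
    final = (
        per_rep.groupby(["construct_id", "target"])
        .agg(
            activation_score=("score", "mean"),
            n_groups=("n_groups", "sum"),
            n_replicates=("replicate", "nunique"),
        )
        .reset_index()
    )
    # report unscored constructs too (coverage statistics matter)
    universe = (
        wide[["construct_id", "target"]].drop_duplicates().reset_index(drop=True)
    )
    final = universe.merge(final, on=["construct_id", "target"], how="left")
    final["n_groups"] = final["n_groups"].fillna(0).astype(int)
    final["n_replicates"] = final["n_replicates"].fillna(0).astype(int)
    return final


def coverage_report(scores: pd.DataFrame) -> pd.DataFrame:
    """Fraction of constructs per target that met the coverage threshold."""
    out = (
        scores.assign(scored=scores["activation_score"].notna())
        .groupby("target")
        .agg(n_constructs=("construct_id", "nunique"), n_scored=("scored", "sum"))
        .reset_index()
    )
    out["fraction_scored"] = out["n_scored"] / out["n_constructs"]
    return out


def toxicity_score(
    reads_cells: float, reads_plasmid: float, pseudoread: float = 1.0, negate: bool = True
) -> float:
    """Signed log2 depletion of a construct in cells vs the plasmid pool."""
    if reads_cells < 0 or reads_plasmid < 0:
        raise ValueError("normalized read counts must be non-negative")
    ratio = (reads_cells + pseudoread) / (reads_plasmid + pseudoread)
    val = np.log2(ratio)
    return float(-val if negate else val)


def score_toxicity_screen(
    table: pd.DataFrame,
    cfg: FilterConfig,
    include_targets: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Toxicity per construct, averaged over target populations x replicates.

    Per (target, replicate): the outlier-UMI filter is applied to the
    unsorted cell counts but not to plasmid counts (plasmid pools carry no
    clonal outliers), all UMIs are pooled into one group, both conditions
    are normalized to a mean of 100 reads over constructs, and the signed
    log2 ratio with one pseudoread is taken. Constructs absent from cells
    but present in plasmid receive a large positive (toxic) score.
    Reporter-derived populations should be excluded via include_targets to
    avoid double-counting cell populations.
    """
    if include_targets is not None:
        table = table[table["target"].isin(include_targets)]
    pairs = table[table["condition"].isin(["unsorted", "plasmid"])]
    rows = []
    for (target, rep), sub in pairs.groupby(["target", "replicate"]):
        cells = sub[sub["condition"] == "unsorted"]
        plasmid = sub[sub["condition"] == "plasmid"]
        if plasmid.empty:
            raise ValueError(f"missing plasmid condition for {target} rep {rep}")
        if cells.empty:
            raise ValueError(f"missing unsorted condition for {target} rep {rep}")
        cells = filter_outlier_umis(cells, cfg)
        c = cells.groupby("construct_id")["count"].sum()
        p = plasmid.groupby("construct_id")["count"].sum()
        universe = c.index.union(p.index)
        c = c.reindex(universe, fill_value=0).astype(float)
        p = p.reindex(universe, fill_value=0).astype(float)
        if c.mean() > 0:  # cells may be empty after outlier filtering
            c *= cfg.normalization_target / c.mean()
        p *= cfg.normalization_target / p.mean()
        ratio = np.log2((c + cfg.pseudoread) / (p + cfg.pseudoread))
        tox = -ratio if cfg.negate_toxicity else ratio
        rows.append(
            pd.DataFrame(
                {
                    "construct_id": universe,
                    "target": target,
                    "replicate": rep,
                    "toxicity": tox.to_numpy(),
                }
            )
        )
    per_pop = pd.concat(rows, ignore_index=True)
    final = (
        per_pop.groupby("construct_id")
        .agg(toxicity_score=("toxicity", "mean"), n_populations=("toxicity", "size"))
        .reset_index()
    )
    return final
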