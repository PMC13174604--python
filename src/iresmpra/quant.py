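"""Replicate combination, input filtering, RPM normalization and TE computation.

Translation efficiency is the ratio of reads-per-million in the
immunoprecipitated (IP) library to RPM in the input library, reported per
construct and cap class — a_cap TE measures IRES activity, g_cap TE measures
cap-dependent initiation. The RPM denominator is the whole sequencing sample
across both cap classes: the two classes come from one co-transfected pool
split in silico, and per-class normalization would erase the genuine global
difference between IRES and CDI recruitment.

Rules applied, in order: technical replicates are summed, then (after
correlation QC) biological replicates; constructs with fewer than
``min_input`` unique-UMI counts in any input library are removed; IP zero
counts are replaced with a small pseudocount (1e-6) before RPM scaling; TE is
IP RPM / input RPM and log2 of that ratio.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_INPUT = 10
DEFAULT_PSEUDOCOUNT = 1e-6

TE_COLUMNS = [
    "construct_id",
    "cap_class",
    "condition",
    "input_count",
    "ip_count",
    "input_rpm",
    "ip_rpm",
    "te_linear",
    "log2_te",
    "filtered_low_input",
    "ip_pseudocounted",
]


class CountMatrix:
    """Unique-UMI molecule counts per (construct, cap class, sample).

    ``counts`` is long-form (construct_id, cap_class, sample_id, count);
    absent rows are zeros. ``samples`` carries the metadata (role input/IP,
    condition, biological and technical replicate).
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.copy()
        samples = samples.copy()
        required = {"construct_id", "cap_class", "sample_id", "count"}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts missing columns {required - set(counts.columns)}")
        if not {"sample_id", "role", "condition"}.issubset(samples.columns):
            raise ValueError("samples must carry sample_id, role, condition")
        for col in ("bio_rep", "tech_rep"):
            if col not in samples.columns:
                samples[col] = "1"
        unknown = set(counts["sample_id"]) - set(samples["sample_id"])
        if unknown:
            raise ValueError(f"counts reference samples not in the sheet: {sorted(unknown)}")
        if (counts["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        bad_cls = set(counts["cap_class"]) - {"a_cap", "g_cap"}
        if bad_cls:
            raise ValueError(f"unknown cap_class values: {sorted(bad_cls)}")
        self.counts = counts.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts, self.samples)

    def sample_meta(self, sample_id: str) -> pd.Series:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t")
        samples = pd.read_csv(samples_path, sep="\t", dtype=str)
        return cls(counts, samples)


def combine_replicates(cm: CountMatrix, level: str) -> CountMatrix:
    """Sum counts across technical or biological replicates.

    ``level='technical'`` sums within (role, condition, bio_rep);
    ``level='biological'`` sums within (role, condition). Metadata collapses
    accordingly and sample ids are rebuilt from the surviving keys.
    """
    if level == "technical":
        keys = ["role", "condition", "bio_rep"]
    elif level == "biological":
        keys = ["role", "condition"]
    else:
        raise ValueError(f"level must be 'technical' or 'biological', got {level!r}")
    meta = cm.samples.set_index("sample_id")
    merged = cm.counts.merge(meta[keys], left_on="sample_id", right_index=True)
    roles_per_group = merged.groupby(keys, dropna=False)["role"].nunique()
    if (roles_per_group > 1).any():
        raise ValueError("merge group mixes input and IP samples")

    def new_id(row) -> str:
        parts = [row["role"], row["condition"]]
        if level == "technical":
            parts.append(f"b{row['bio_rep']}")
        return "_".join(str(p) for p in parts)

    merged["sample_id"] = merged.apply(new_id, axis=1)
    counts = (
        merged.groupby(["construct_id", "cap_class", "sample_id"], as_index=False)["count"]
        .sum()
    )
    samples = merged[["sample_id"] + keys].drop_duplicates().reset_index(drop=True)
    if "bio_rep" not in samples.columns:
        samples["bio_rep"] = "all"
    samples["tech_rep"] = "all"
    return CountMatrix(counts, samples)


def filter_low_input(
    cm: CountMatrix,
    min_input: int = DEFAULT_MIN_INPUT,
    constructs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Flag (construct, cap_class) rows with < ``min_input`` counts in any input library.

    Returns a DataFrame (construct_id, cap_class, filtered_low_input). The
    universe of rows defaults to every (construct, cap_class) observed in any
    sample; pass ``constructs`` to force a larger universe (absent counts are
    zeros and therefore filtered).
    """
    input_samples = cm.samples.loc[cm.samples["role"] == "input", "sample_id"]
    if input_samples.empty:
        raise ValueError("no input samples present")
    if constructs is None:
        universe = cm.counts[["construct_id", "cap_class"]].drop_duplicates()
    else:
        universe = pd.DataFrame(constructs, columns=["construct_id", "cap_class"])
    pivot = (
        cm.counts[cm.counts["sample_id"].isin(input_samples)]
        .pivot_table(
            index=["construct_id", "cap_class"],
            columns="sample_id",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(pd.MultiIndex.from_frame(universe), fill_value=0)
        .reindex(columns=list(input_samples), fill_value=0)
    )
    flags = universe.copy()
    flags["filtered_low_input"] = (pivot.to_numpy() < min_input).any(axis=1)
    return flags.reset_index(drop=True)


def compute_rpm(
    cm: CountMatrix,
    flags: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Reads-per-million per retained (construct, cap_class, sample).

    Within each sample the denominator is the total retained count across
    both cap classes. For IP samples, zero counts among retained rows are
    replaced by ``pseudocount`` before scaling and flagged. Returns a long
    DataFrame: construct_id, cap_class, sample_id, count, rpm,
    ip_pseudocounted.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    retained = flags.loc[~flags["filtered_low_input"], ["construct_id", "cap_class"]]
    if retained.empty:
        raise ValueError("input filter removed every construct")
    out_frames = []
    for srow in cm.samples.itertuples(index=False):
        sid = srow.sample_id
        sub = cm.counts[cm.counts["sample_id"] == sid]
        grid = retained.merge(
            sub[["construct_id", "cap_class", "count"]], on=["construct_id", "cap_class"], how="left"
        )
        grid["count"] = grid["count"].fillna(0.0)
        grid["sample_id"] = sid
        grid["ip_pseudocounted"] = False
        numer = grid["count"].astype(float)
        if srow.role == "IP":
            zero = numer == 0
            numer = numer.where(~zero, pseudocount)
            grid["ip_pseudocounted"] = zero
        total = numer.sum()
        if total <= 0:
            raise ValueError(f"sample {sid!r} has zero total retained counts")
        grid["rpm"] = numer * 1e6 / total
        out_frames.append(grid)
    return pd.concat(out_frames, ignore_index=True)


def compute_te(
    rpm: pd.DataFrame,
    samples: pd.DataFrame,
    flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """TE table from matched input/IP RPM values, one row per
    (construct, cap_class, condition).

    te_linear = ip_rpm / input_rpm and log2_te = log2(te_linear), computed
    independently per cap class so each construct gets an IRES TE (a_cap) and
    a CDI TE (g_cap). Expects exactly one input and one IP sample per
    condition (i.e. replicates already combined). Rows removed by the input
    filter are appended with NaN TE and the filter flag set.
    """
    meta = samples.set_index("sample_id")
    df = rpm.merge(meta[["role", "condition"]], left_on="sample_id", right_index=True)
    tables = []
    for cond, sub in df.groupby("condition"):
        inp = sub[sub["role"] == "input"]
        ip = sub[sub["role"] == "IP"]
        if inp["sample_id"].nunique() != 1 or ip["sample_id"].nunique() != 1:
            raise ValueError(
                f"condition {cond!r} needs exactly one combined input and one IP sample"
            )
        m = inp[["construct_id", "cap_class", "count", "rpm"]].merge(
            ip[["construct_id", "cap_class", "count", "rpm", "ip_pseudocounted"]],
            on=["construct_id", "cap_class"],
            suffixes=("_input", "_ip"),
        )
        if (m["rpm_input"] <= 0).any():
            bad = m.loc[m["rpm_input"] <= 0, "construct_id"].iloc[0]
            raise ValueError(
                f"retained construct {bad!r} has zero input RPM (precluded by the input filter)"
            )
        te = pd.DataFrame(
            {
                "construct_id": m["construct_id"],
                "cap_class": m["cap_class"],
                "condition": cond,
                "input_count": m["count_input"],
                "ip_count": m["count_ip"],
                "input_rpm": m["rpm_input"],
                "ip_rpm": m["rpm_ip"],
                "te_linear": m["rpm_ip"] / m["rpm_input"],
                "log2_te": np.log2(m["rpm_ip"] / m["rpm_input"]),
                "filtered_low_input": False,
                "ip_pseudocounted": m["ip_pseudocounted"],
            }
        )
        if flags is not None:
            dropped = flags[flags["filtered_low_input"]]
            if not dropped.empty:
                pad = pd.DataFrame(
                    {
                        "construct_id": dropped["construct_id"],
                        "cap_class": dropped["cap_class"],
                        "condition": cond,
                        "input_count": np.nan,
                        "ip_count": np.nan,
                        "input_rpm": np.nan,
                        "ip_rpm": np.nan,
                        "te_linear": np.nan,
                        "log2_te": np.nan,
                        "filtered_low_input": True,
                        "ip_pseudocounted": False,
                    }
                )
                te = pd.concat([te, pad], ignore_index=True)
        tables.append(te)
    return pd.concat(tables, ignore_index=True)[TE_COLUMNS]


def te_pipeline(
    cm: CountMatrix,
    min_input: int = DEFAULT_MIN_INPUT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    combine: str = "biological",
) -> pd.DataFrame:
    """Convenience wrapper: combine replicates, filter, normalize, compute TE."""
    combined = combine_replicates(cm, "technical")
    if combine == "biological":
        combined = combine_replicates(combined, "biological")
    flags = filter_low_input(combined, min_input)
    rpm = compute_rpm(combined, flags, pseudocount)
    return compute_te(rpm, combined.samples, flags)


def replicate_correlation(te_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson r of log2 TE across replicate TE tables.

    Constructs with zero reads in the IP library of either replicate of a
    pair are excluded from that pair's correlation, as are filtered rows.
    Returns a DataFrame (rep_a, rep_b, pearson_r, n_constructs).
    """
    if len(te_tables) < 2:
        raise ValueError("need at least two replicates to correlate")
    rows = []
    for (na, ta), (nb, tb) in itertools.combinations(te_tables.items(), 2):
        cols = ["construct_id", "cap_class", "log2_te", "ip_count", "filtered_low_input"]
        m = ta[cols].merge(tb[cols], on=["construct_id", "cap_class"], suffixes=("_a", "_b"))
        ok = (
            (m["ip_count_a"] > 0)
            & (m["ip_count_b"] > 0)
            & ~m["filtered_low_input_a"]
            & ~m["filtered_low_input_b"]
        )
        m = m[ok]
        if len(m) < 2:
            raise ValueError(f"replicates {na!r}/{nb!r} share fewer than 2 usable constructs")
        r = float(np.corrcoef(m["log2_te_a"], m["log2_te_b"])[0, 1])
        rows.append({"rep_a": na, "rep_b": nb, "pearson_r": r, "n_constructs": len(m)})
    return pd.DataFrame(rows)


def normalize_luciferase(nluc, fluc, nluc_bg, fluc_bg):
    """Background-subtracted N-luc / F-luc ratio.

    Backgrounds come from untransfected wells; a non-positive F-luc
    denominator is an error (no signal over background to normalize by).
    """
    nluc = np.asarray(nluc, dtype=float)
    fluc = np.asarray(fluc, dtype=float)
    denom = fluc - np.asarray(fluc_bg, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("F-luc signal does not exceed background")
    ratio = (nluc - np.asarray(nluc_bg, dtype=float)) / denom
    return float(ratio) if ratio.ndim == 0 else ratio
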