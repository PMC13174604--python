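"""Activity classification, mutagenesis profiles and structure statistics.

The activity threshold follows the assay's convention: a construct is called
an active IRES if its a_cap TE is at least that of the CrPV IRES measured in
the same experiment — CrPV is a weak but bona fide viral IRES in human cells,
so anything below it is indistinguishable from assay background. The
IRES-as-percent-of-CDI statistic (100 x a_cap TE / g_cap TE) separates real
internal initiation from the faint background signal that trails every
well-translated G-cap reporter.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .reference import PairedRegion, parse_window_id
from .structures import SecondaryStructure

logger = logging.getLogger(__name__)


def _te_lookup(te_table: pd.DataFrame, cap_class: str) -> pd.Series:
    sub = te_table[
        (te_table["cap_class"] == cap_class) & ~te_table["filtered_low_input"].astype(bool)
    ]
    return sub.set_index("construct_id")["te_linear"]


def classify_active(
    te_table: pd.DataFrame, threshold_construct: str = "CrPV"
) -> pd.DataFrame:
    """Active/inactive calls against the threshold construct's a_cap TE.

    The comparison is inclusive: a construct exactly at the threshold drives
    "at least as much" translation and is active (so the threshold construct
    itself always is). Returns construct_id, ires_te, cdi_te, pct_cdi,
    active, threshold_te.
    """
    ires = _te_lookup(te_table, "a_cap")
    cdi = _te_lookup(te_table, "g_cap")
    if threshold_construct not in ires.index:
        raise ValueError(
            f"threshold construct {threshold_construct!r} absent or filtered from a_cap TE"
        )
    thr = float(ires[threshold_construct])
    out = pd.DataFrame({"construct_id": ires.index, "ires_te": ires.values})
    out["cdi_te"] = out["construct_id"].map(cdi)
    out["pct_cdi"] = 100.0 * out["ires_te"] / out["cdi_te"]
    out["active"] = out["ires_te"] >= thr
    out["threshold_te"] = thr
    return out.reset_index(drop=True)


def ires_pct_cdi(te_table: pd.DataFrame) -> pd.Series:
    """IRES TE as a percentage of CDI TE per construct (100 x a_cap/g_cap).

    Constructs whose g_cap row is filtered/absent are omitted with a warning.
    """
    ires = _te_lookup(te_table, "a_cap")
    cdi = _te_lookup(te_table, "g_cap")
    shared = ires.index.intersection(cdi.index)
    missing = ires.index.difference(cdi.index)
    if len(missing):
        logger.warning(
            "ires_pct_cdi: %d construct(s) lack a usable g_cap TE and were omitted", len(missing)
        )
    return (100.0 * ires[shared] / cdi[shared]).rename("pct_cdi")


def mutagenesis_profile(
    te_table: pd.DataFrame,
    manifest: pd.DataFrame,
    wildtype_id: str | None = None,
) -> dict:
    """Fold-change of IRES (a_cap) TE per scanning window, mapped to window centers.

    ``manifest`` needs columns construct_id, start, end (1-based closed
    windows) and optionally wildtype_id; window coordinates may instead be
    encoded in the variant ids. fold_change = variant TE / wildtype TE, so
    values below 1 are decreases. The per-position track assigns each
    window's fold change to its center nucleotide, floor((start+end)/2) —
    e.g. position 2 for window 1-3.

    Returns ``{"windows": DataFrame, "track": DataFrame, "min_fold": float,
    "max_fold": float, "wildtype_id": str}``; missing variants leave gaps
    with a warning, a missing wildtype is an error.
    """
    ires = _te_lookup(te_table, "a_cap")
    manifest = manifest.copy()
    if wildtype_id is None:
        if "wildtype_id" not in manifest.columns or manifest["wildtype_id"].nunique() != 1:
            raise ValueError("wildtype_id must be given or unique in the manifest")
        wildtype_id = str(manifest["wildtype_id"].iloc[0])
    if wildtype_id not in ires.index:
        raise ValueError(f"wildtype {wildtype_id!r} absent or filtered from a_cap TE")
    wt_te = float(ires[wildtype_id])
    if {"start", "end"} - set(manifest.columns):
        coords = manifest["construct_id"].map(parse_window_id)
        manifest["start"] = [c[0] for c in coords]
        manifest["end"] = [c[1] for c in coords]
    rows = []
    missing = []
    for r in manifest.itertuples(index=False):
        if r.construct_id == wildtype_id:
            continue
        if r.construct_id not in ires.index:
            missing.append(r.construct_id)
            continue
        s, e = int(r.start), int(r.end)
        fold = float(ires[r.construct_id]) / wt_te
        rows.append(
            {
                "construct_id": r.construct_id,
                "start": s,
                "end": e,
                "center": (s + e) // 2,
                "fold_change": fold,
            }
        )
    if missing:
        logger.warning("mutagenesis_profile: %d variant(s) missing from TE table", len(missing))
    windows = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
    if windows.empty:
        raise ValueError("no scanning variants with usable TE values")
    track = windows[["center", "fold_change"]].rename(columns={"center": "position"})
    return {
        "windows": windows,
        "track": track.reset_index(drop=True),
        "min_fold": float(windows["fold_change"].min()),
        "max_fold": float(windows["fold_change"].max()),
        "wildtype_id": wildtype_id,
    }


def helix_rescue(
    te_table: pd.DataFrame,
    region: PairedRegion,
    l_id: str,
    r_id: str,
    c_id: str,
    wildtype_id: str,
) -> dict:
    """Compensatory-rescue report for one helix's L/R/C mutant trio.

    rescue_index = te_C / sqrt(te_L x te_R): 1 means the compensatory double
    mutant is no better than the geometric mean of the two disruptions, i.e.
    no rescue. restoration_fraction places log2 te_C on the scale from the
    disrupted baseline (mean of log2 te_L, log2 te_R; value 0) to the
    wildtype (value 1), clipped to [0, 1.5] for reporting.
    """
    ires = _te_lookup(te_table, "a_cap")
    tes = {}
    for name, cid in (("L", l_id), ("R", r_id), ("C", c_id), ("WT", wildtype_id)):
        if cid not in ires.index:
            raise ValueError(f"{name} construct {cid!r} absent or filtered from a_cap TE")
        tes[name] = float(ires[cid])
    baseline = 0.5 * (math.log2(tes["L"]) + math.log2(tes["R"]))
    span = math.log2(tes["WT"]) - baseline
    rescue_index = tes["C"] / math.sqrt(tes["L"] * tes["R"])
    if span == 0:
        restoration = float("nan")
    else:
        restoration = (math.log2(tes["C"]) - baseline) / span
        restoration = min(max(restoration, 0.0), 1.5)
    return {
        "region": region.name,
        "te_L": tes["L"],
        "te_R": tes["R"],
        "te_C": tes["C"],
        "te_WT": tes["WT"],
        "rescue_index": rescue_index,
        "restoration_fraction": restoration,
    }


def gc_pair_fraction(structure: SecondaryStructure) -> float:
    """Percentage of base pairs that are strong G-C pairs (either orientation).

    G-U wobbles count as non-strong but stay in the denominator; pseudoknot
    pairs are included. A structure with no pairs has no defined fraction and
    raises.
    """
    if not structure.pairs:
        raise ValueError(f"structure {structure.structure_id!r} has no base pairs")
    seq = structure.sequence
    strong = sum(
        1 for i, j in structure.pairs if {seq[i - 1], seq[j - 1]} == {"G", "C"}
    )
    return 100.0 * strong / len(structure.pairs)


def compare_gc_groups(fractions: pd.Series, calls: pd.DataFrame) -> dict:
    """One-sided rank-sum test: do active IRESes have more strong G-C pairs?

    ``fractions`` is indexed by construct_id; ``calls`` comes from
    :func:`classify_active`. Uses the exact Mann-Whitney null for small,
    tie-free groups (e.g. complete 2-vs-2 separation gives p = 1/6), the
    normal approximation otherwise.
    """
    labels = calls.set_index("construct_id")["active"]
    shared = fractions.index.intersection(labels.index)
    active = fractions[shared][labels[shared]].to_numpy(dtype=float)
    inactive = fractions[shared][~labels[shared]].to_numpy(dtype=float)
    if len(active) < 2 or len(inactive) < 2:
        raise ValueError(
            f"need >=2 constructs per group, got {len(active)} active / {len(inactive)} inactive"
        )
    res = stats.mannwhitneyu(active, inactive, alternative="greater")
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_active": int(len(active)),
        "n_inactive": int(len(inactive)),
        "median_active": float(np.median(active)),
        "median_inactive": float(np.median(inactive)),
        "test": "one-sided Mann-Whitney rank-sum (active > inactive)",
    }
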