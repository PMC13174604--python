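"""Spike-in-anchored normalization across conditions and differential TE.

RPM-based TE is compositional: a global change in translation moves every
construct's RPM share but leaves the ratios untouched, so stress-induced
global suppression is invisible to within-sample normalization. The three
G-cap spike-in reporters break that degeneracy. They come from one unstressed
lysate added to every sample at a fixed fraction, so their ribosome loading is
condition-independent; any apparent change in their TE between conditions
measures the global shift of the rest of the library (plus technical IP
differences), and dividing it out puts all conditions on one scale.

The fitted factor per condition is the geometric mean over the three spikes of
``te_spike(condition) / te_spike(reference)`` — i.e. the fold by which the
library's translation globally dropped (a factor of 2 means a uniform 2x
suppression). Adjusted TE is ``te / factor``; the reference condition has
factor 1 by construction. The geometric mean is the natural average on a
3-point log-scale dilution series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DESIGNED_SPIKE_RATIO = (0.01, 0.1, 1.0)


@dataclass(frozen=True)
class SpikeInSet:
    """The three serially diluted G-cap spike-in constructs.

    ``designed_rel_abundance`` is the dilution design up to scale (spike 1 is
    100-fold below spike 3, spike 2 ten-fold below). After fitting,
    ``fitted_factor[condition]`` is the global suppression factor relative to
    ``reference`` and ``linearity_r2[condition]`` the goodness of fit of
    observed vs designed log input abundances.
    """

    spike_ids: tuple[str, str, str]
    designed_rel_abundance: tuple[float, float, float] = DESIGNED_SPIKE_RATIO
    reference: str | None = None
    fitted_factor: dict = field(default_factory=dict)
    linearity_r2: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.spike_ids) != 3 or len(set(self.spike_ids)) != 3:
            raise ValueError("exactly three distinct spike-in ids required")
        a = self.designed_rel_abundance
        if not (0 < a[0] < a[1] < a[2]):
            raise ValueError("designed abundances must be positive and strictly increasing")
        for cond, f in self.fitted_factor.items():
            if f <= 0:
                raise ValueError(f"fitted factor for {cond!r} must be positive")
        if self.fitted_factor and self.reference is not None:
            ref = self.fitted_factor.get(self.reference)
            if ref is not None and not np.isclose(ref, 1.0):
                raise ValueError("reference condition must have factor 1")

    def factor(self, condition: str) -> float:
        try:
            return self.fitted_factor[condition]
        except KeyError:
            raise KeyError(
                f"no fitted factor for condition {condition!r}; run fit_spikein_factors"
            ) from None


def _spike_te(te_table: pd.DataFrame, spike_id: str) -> float:
    row = te_table[
        (te_table["construct_id"] == spike_id) & (te_table["cap_class"] == "g_cap")
    ]
    if row.empty:
        raise ValueError(f"spike-in {spike_id!r} absent from TE table")
    r = row.iloc[0]
    if bool(r["filtered_low_input"]) or not np.isfinite(r["te_linear"]):
        raise ValueError(f"spike-in {spike_id!r} was filtered or has no TE")
    if r["input_count"] <= 0:
        raise ValueError(f"spike-in {spike_id!r} has zero input counts")
    return float(r["te_linear"])


def fit_spikein_factors(
    te_tables: dict[str, pd.DataFrame],
    spikes: SpikeInSet,
    reference: str,
    weights: str = "designed",
) -> SpikeInSet:
    """Fit per-condition normalization factors from spike-in TEs.

    ``te_tables`` maps condition name to its TE table. The factor for each
    condition is a geometric mean over the three spikes of
    te(condition)/te(reference); the reference gets exactly 1.

    ``weights='designed'`` (default) weights each spike's log ratio by its
    designed relative abundance — the sampling variance of a spike's TE
    scales inversely with its molecule count, so this is approximately
    inverse-variance weighting and keeps the 100x-diluted spike from
    dominating the noise. ``weights='equal'`` is the plain geometric mean.

    Linearity r2 regresses observed log spike input RPM on designed log
    abundance within each condition (a sanity check that the dilution series
    survived the experiment).
    """
    if reference not in te_tables:
        raise ValueError(f"reference condition {reference!r} not among TE tables")
    if weights == "designed":
        w = np.asarray(spikes.designed_rel_abundance, dtype=float)
    elif weights == "equal":
        w = np.ones(3)
    else:
        raise ValueError(f"weights must be 'designed' or 'equal', got {weights!r}")
    w = w / w.sum()
    ref_te = {sid: _spike_te(te_tables[reference], sid) for sid in spikes.spike_ids}
    factors: dict[str, float] = {}
    r2: dict[str, float] = {}
    log_design = np.log10(spikes.designed_rel_abundance)
    for cond, table in te_tables.items():
        ratios = []
        rpms = []
        for sid in spikes.spike_ids:
            te = _spike_te(table, sid)
            ratios.append(te / ref_te[sid])
            row = table[
                (table["construct_id"] == sid) & (table["cap_class"] == "g_cap")
            ].iloc[0]
            rpms.append(float(row["input_rpm"]))
        factors[cond] = float(np.exp(np.sum(w * np.log(ratios))))
        fit = stats.linregress(log_design, np.log10(rpms))
        r2[cond] = float(fit.rvalue**2)
    factors[reference] = 1.0
    return replace(spikes, reference=reference, fitted_factor=factors, linearity_r2=r2)


def adjust_te(te_table: pd.DataFrame, spikes: SpikeInSet, condition: str) -> pd.DataFrame:
    """Divide a condition's TEs by its fitted factor (reference is unchanged)."""
    f = spikes.factor(condition)
    out = te_table.copy()
    out["te_linear"] = out["te_linear"] / f
    out["log2_te"] = out["log2_te"] - np.log2(f)
    out["spikein_factor"] = f
    return out


def _pct_cdi(te_table: pd.DataFrame) -> pd.Series:
    wide = te_table.pivot_table(index="construct_id", columns="cap_class", values="te_linear")
    if "a_cap" not in wide or "g_cap" not in wide:
        return pd.Series(dtype=float)
    return 100.0 * wide["a_cap"] / wide["g_cap"]


def differential_te(
    adjusted_control: pd.DataFrame, adjusted_stress: pd.DataFrame
) -> pd.DataFrame:
    """Per-(construct, cap class) log2 fold-change of adjusted TE, stress vs control.

    Also reports each construct's IRES-as-percent-of-CDI statistic under both
    conditions. Constructs missing (or filtered) in either condition are
    omitted with a logged warning.
    """
    cols = ["construct_id", "cap_class", "te_linear", "filtered_low_input"]
    m = adjusted_control[cols].merge(
        adjusted_stress[cols], on=["construct_id", "cap_class"], suffixes=("_control", "_stress")
    )
    usable = (
        ~m["filtered_low_input_control"]
        & ~m["filtered_low_input_stress"]
        & np.isfinite(m["te_linear_control"])
        & np.isfinite(m["te_linear_stress"])
    )
    n_all = {
        (r.construct_id, r.cap_class)
        for t in (adjusted_control, adjusted_stress)
        for r in t.itertuples()
    }
    n_used = int(usable.sum())
    if n_used < len(n_all):
        logger.warning(
            "differential TE: %d of %d (construct, cap_class) rows usable in both conditions",
            n_used,
            len(n_all),
        )
    m = m[usable]
    pct_c = _pct_cdi(adjusted_control)
    pct_s = _pct_cdi(adjusted_stress)
    out = pd.DataFrame(
        {
            "construct_id": m["construct_id"],
            "cap_class": m["cap_class"],
            "te_control": m["te_linear_control"],
            "te_stress_adjusted": m["te_linear_stress"],
            "log2_fc": np.log2(m["te_linear_stress"] / m["te_linear_control"]),
        }
    )
    out["pct_cdi_control"] = out["construct_id"].map(pct_c)
    out["pct_cdi_stress"] = out["construct_id"].map(pct_s)
    return out.reset_index(drop=True)
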