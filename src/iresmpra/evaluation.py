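"""Self-contained benchmark experiments on fully synthetic data.

Each function simulates a dataset with :mod:`iresmpra.simulate`, runs the
pipeline on it, and measures how well a known ground truth is recovered:

* UMI-count oracle equivalence — pipeline counts vs an independent tally of
  distinct (construct, cap class, UMI) triples from the simulator sidecar;
* error-free channel — with substitution rate 0, demultiplexing and
  construct assignment must reproduce the sidecar labels exactly;
* TE parameter recovery — rank agreement and RMSE of estimated vs expected
  log2 TE at realistic depth;
* spike-in recovery — dilution-series ratios from input RPM, and detection
  of a uniform global translation drop via the spike-anchored factor;
* filter / pseudocount boundary behaviour and the design-rule algebra.

Everything is deterministic given the seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .quant import CountMatrix, compute_rpm, compute_te, filter_low_input, te_pipeline
from .readproc import process_pairs
from .reference import PairedRegion, design_helix_mutants, design_scanning_mutants
from .simulate import SimConfig, build_truth, generate_read_pairs, random_library
from .stress import SpikeInSet, adjust_te, differential_te, fit_spikein_factors
from .structfunc import compare_gc_groups, gc_pair_fraction
from .structures import parse_dotbracket


def _simulate_and_process(truth, library, samples, collect=False):
    """samples: list of (role, sample_id, condition). Returns per-sample results
    plus sidecar label lists."""
    out = {}
    for role, sid, cond in samples:
        sidecar = []

        def stream():
            for rid, s1, s2, cid, cls, umi, mol in generate_read_pairs(
                truth, library, role, sid, cond
            ):
                sidecar.append((rid, cid, cls, umi))
                yield rid, s1, s2

        res = process_pairs(stream(), library, sid, collect_assignments=collect)
        out[sid] = (res, sidecar)
    return out


def _count_matrix(results, samples):
    counts = pd.concat([results[sid][0].counts for _, sid, _ in samples], ignore_index=True)
    meta = pd.DataFrame(
        [
            {"sample_id": sid, "role": role, "condition": cond, "bio_rep": "1", "tech_rep": "1"}
            for role, sid, cond in samples
        ]
    )
    return CountMatrix(counts, meta)


def umi_count_oracle(seed: int, n_reads: int) -> dict:
    """Max |pipeline count − brute-force distinct-triple tally| over one
    error-free input+IP dataset (PCR duplicates and staggers included)."""
    library = random_library(30, 100, seed)
    cfg = SimConfig(reads_per_sample=n_reads, epsilon=0.0, duplication_mean=2.0)
    truth = build_truth(library, cfg, seed)
    samples = [("input", "oracle_in", "control"), ("IP", "oracle_ip", "control")]
    results = _simulate_and_process(truth, library, samples)
    max_diff = 0
    n_keys = 0
    for sid, (res, sidecar) in results.items():
        brute: dict[tuple, set] = {}
        for rid, cid, cls, umi in sidecar:
            brute.setdefault((cid, cls), set()).add(umi)
        expected = {k: len(v) for k, v in brute.items()}
        got = {(r.construct_id, r.cap_class): r.count for r in res.counts.itertuples()}
        keys = set(expected) | set(got)
        n_keys += len(keys)
        for k in keys:
            max_diff = max(max_diff, abs(expected.get(k, 0) - got.get(k, 0)))
    return {"max_abs_diff": max_diff, "n_keys": n_keys, "n_reads": n_reads}


def errorfree_recovery(seed: int, n_reads: int = 20000) -> dict:
    """Per-read label recovery at epsilon = 0, against the simulator sidecar."""
    library = random_library(40, 120, seed)
    cfg = SimConfig(reads_per_sample=n_reads, epsilon=0.0)
    truth = build_truth(library, cfg, seed)
    samples = [("input", "ef_in", "control"), ("IP", "ef_ip", "control")]
    results = _simulate_and_process(truth, library, samples, collect=True)
    n_total = n_wrong = 0
    partition_ok = True
    for sid, (res, sidecar) in results.items():
        rep = res.report
        partition_ok &= rep["a_cap"] + rep["g_cap"] + rep["unassigned"] == rep["total"]
        for rid, cid, cls, umi in sidecar:
            n_total += 1
            if res.assignments[rid] != (cls, cid):
                n_wrong += 1
    return {"misassigned_reads": n_wrong, "n_reads": n_total, "partition_ok": int(partition_ok)}


def te_recovery(seed: int, n_candidates: int = 495, n_reads: int = 1_000_000) -> dict:
    """Spearman and RMSE of estimated vs expected log2 TE.

    ~500 constructs, true log2 TE ~ Uniform(−5, 5), 10^6 read pairs per
    sample. Spearman runs over every retained row; RMSE over rows with at
    least 100 input UMIs and a nonzero IP observation (zero-IP rows carry a
    pseudocount artifact, not an estimate).
    """
    library = random_library(n_candidates, 150, seed)
    cfg = SimConfig(reads_per_sample=n_reads)
    truth = build_truth(library, cfg, seed)
    samples = [("input", "rec_in", "control"), ("IP", "rec_ip", "control")]
    results = _simulate_and_process(truth, library, samples)
    te = te_pipeline(_count_matrix(results, samples))
    est = te[~te["filtered_low_input"]].set_index(["construct_id", "cap_class"])
    joined = est.join(truth.expected_log2_te("control"), how="inner").dropna(
        subset=["log2_te", "expected_log2_te"]
    )
    rho = float(sstats.spearmanr(joined["log2_te"], joined["expected_log2_te"]).statistic)
    deep = joined[(joined["input_count"] >= 100) & ~joined["ip_pseudocounted"]]
    err2 = (deep["log2_te"] - deep["expected_log2_te"]) ** 2
    rmse = float(np.sqrt(err2.mean()))
    # Poisson sampling floor implied by the realized molecule counts: the
    # ratio estimator cannot beat this, whatever the depth restriction
    floor = float(
        np.sqrt(np.mean((1 / np.log(2) ** 2) * (1 / deep["ip_count"] + 1 / deep["input_count"])))
    )
    well_covered = deep["ip_count"] >= 10
    return {
        "spearman": rho,
        "rmse_log2": rmse,
        "rmse_log2_ip_covered": float(np.sqrt(err2[well_covered].mean())),
        "rmse_sampling_floor": floor,
        "n_rows": len(joined),
        "n_deep": len(deep),
        "n_reads": n_reads,
    }


def spike_dilution_recovery(seed: int, n_spike_reads: int = 100_000) -> dict:
    """Recovery of the designed 1:10:100 spike ratios from input RPM.

    Spikes are given half the sample so the stated spike read count is
    reached at desk scale; the dilution ratios themselves are the designed
    ones.
    """
    library = random_library(50, 100, seed)
    cfg = SimConfig(
        reads_per_sample=2 * n_spike_reads, epsilon=0.0, duplication_mean=1.0,
        spike_fraction=0.5,
    )
    truth = build_truth(library, cfg, seed)
    samples = [("input", "dil_in", "control")]
    results = _simulate_and_process(truth, library, samples)
    counts = results["dil_in"][0].counts.set_index("construct_id")["count"]
    r31 = counts["spike3"] / counts["spike1"]
    r32 = counts["spike3"] / counts["spike2"]
    err = 100.0 * max(abs(r31 / 100.0 - 1.0), abs(r32 / 10.0 - 1.0))
    return {
        "ratio_3_vs_1": float(r31),
        "ratio_3_vs_2": float(r32),
        "max_rel_error_pct": float(err),
        "spike_reads": int(counts[["spike1", "spike2", "spike3"]].sum()),
    }


def stress_factor_recovery(seed: int, n_reads: int = 800_000) -> dict:
    """Detection of a uniform 2x translational drop via the spike anchor.

    All library constructs have true TE 1; under stress every non-spike
    construct except five low-abundance stress-resistant ones is halved.
    The spike-anchored factor should read ~2 and the adjusted log2
    fold-change should be ~0 for the resistant (unaffected) constructs and
    ~−1 for the suppressed ones.
    """
    library = random_library(100, 100, seed)
    resistant = [f"cand{i:04d}" for i in range(5)]
    fixed_te = {
        (rec.construct_id, cls): 1.0
        for rec in library
        if not rec.is_spike_in
        for cls in ("a_cap", "g_cap")
    }
    fixed_ab = {
        (cid, cls): 0.1 for cid in resistant for cls in ("a_cap", "g_cap")
    }
    fixed_ab.update(
        {
            (rec.construct_id, cls): 1.0
            for rec in library
            if not rec.is_spike_in and rec.construct_id not in resistant
            for cls in ("a_cap", "g_cap")
        }
    )
    cfg = SimConfig(
        reads_per_sample=n_reads,
        epsilon=0.0,
        duplication_mean=1.0,
        fixed_te=fixed_te,
        fixed_abundance=fixed_ab,
        conditions={
            "control": {},
            "stress": {"te_scale": 0.5, "exempt_ids": resistant},
        },
    )
    truth = build_truth(library, cfg, seed)
    samples = [
        ("input", "in_ctrl", "control"),
        ("IP", "ip_ctrl", "control"),
        ("input", "in_str", "stress"),
        ("IP", "ip_str", "stress"),
    ]
    results = _simulate_and_process(truth, library, samples)
    cm = _count_matrix(results, samples)
    te = te_pipeline(cm)
    tables = {str(c): t.reset_index(drop=True) for c, t in te.groupby("condition")}
    spikes = fit_spikein_factors(tables, SpikeInSet(("spike1", "spike2", "spike3")), "control")
    adjusted = {c: adjust_te(t, spikes, c) for c, t in tables.items()}
    diff = differential_te(adjusted["control"], adjusted["stress"])
    lib_rows = diff[~diff["construct_id"].str.startswith("spike")]
    unaff = lib_rows[lib_rows["construct_id"].isin(resistant)]
    affected = lib_rows[~lib_rows["construct_id"].isin(resistant)]
    return {
        "fitted_factor": float(spikes.fitted_factor["stress"]),
        "unaffected_mean_delta": float(unaff["log2_fc"].mean()),
        "affected_mean_delta": float(affected["log2_fc"].mean()),
        "linearity_r2": float(min(spikes.linearity_r2.values())),
        "n_reads": n_reads,
    }


def boundary_behaviour() -> dict:
    """Input filter at the 9/10 boundary, IP pseudocounting, RPM conservation."""
    samples = pd.DataFrame(
        {
            "sample_id": ["in_a", "in_b", "ip_a"],
            "role": ["input", "input", "IP"],
            "condition": ["control"] * 3,
            "bio_rep": ["1"] * 3,
            "tech_rep": ["1"] * 3,
        }
    )
    counts = pd.DataFrame(
        [
            ("edge9", "a_cap", "in_a", 9), ("edge9", "a_cap", "in_b", 1000),
            ("edge10", "a_cap", "in_a", 10), ("edge10", "a_cap", "in_b", 10),
            ("zeroip", "a_cap", "in_a", 500), ("zeroip", "a_cap", "in_b", 500),
            ("normal", "a_cap", "in_a", 400), ("normal", "a_cap", "in_b", 400),
            ("zeroip", "a_cap", "ip_a", 0), ("normal", "a_cap", "ip_a", 900),
        ],
        columns=["construct_id", "cap_class", "sample_id", "count"],
    )
    cm = CountMatrix(counts, samples)
    flags_df = filter_low_input(cm)
    flags = flags_df.set_index("construct_id")["filtered_low_input"]
    rpm = compute_rpm(cm, flags_df)
    # TE over the in_a/ip_a pair (in_b only participates in the filter)
    te = compute_te(rpm, samples.iloc[[0, 2]])
    zerorow = te[te["construct_id"] == "zeroip"].iloc[0]
    rpm_dev = max(abs(sub["rpm"].sum() - 1e6) for _, sub in rpm.groupby("sample_id"))
    return {
        "count9_removed": int(bool(flags["edge9"])),
        "count10_retained": int(not flags["edge10"]),
        "zero_ip_flagged": int(bool(zerorow["ip_pseudocounted"])),
        "zero_ip_te_finite": int(np.isfinite(zerorow["log2_te"])),
        "rpm_total_max_deviation": float(rpm_dev),
    }


def design_algebra(seed: int = 0) -> dict:
    """Closed-form variant counts, involution/composition identities, and the
    hand-computable structure statistics."""
    rng = np.random.default_rng(seed)
    wt = "".join(rng.choice(list("ACGT"), 120))
    recs = design_scanning_mutants(wt, 4, 3, "transversion_swap")
    count_ok = len(recs) - 1 == (120 - 4) // 3 + 1
    # involution: applying the rule to each variant's window restores wildtype
    from .reference import parse_window_id, transversion_swap

    invol_ok = all(
        wt == r.utr_sequence[: s - 1] + transversion_swap(r.utr_sequence[s - 1 : e]) + r.utr_sequence[e:]
        for r in recs[:-1]
        for s, e in [parse_window_id(r.construct_id)]
    )
    region = PairedRegion("h", (5, 10), (30, 35))
    l_rec, r_rec, c_rec = design_helix_mutants(wt, region)
    from .reference import _mutate_interval

    comp_ok = c_rec.utr_sequence == _mutate_interval(l_rec.utr_sequence, region.right)
    s = parse_dotbracket("demo", "GATCTC", "((..))")
    gc = gc_pair_fraction(s)  # pairs G-C and A-T -> 50%
    fr = pd.Series({"a1": 80.0, "a2": 90.0, "i1": 10.0, "i2": 20.0})
    calls = pd.DataFrame(
        {"construct_id": ["a1", "a2", "i1", "i2"], "active": [True, True, False, False]}
    )
    p = compare_gc_groups(fr, calls)["p_value"]
    return {
        "scan_count_ok": int(count_ok),
        "involution_ok": int(invol_ok),
        "composition_ok": int(comp_ok),
        "gc_pair_fraction_demo": float(gc),
        "ranksum_exact_p": float(p),
    }
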