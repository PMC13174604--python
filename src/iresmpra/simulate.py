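"""Synthetic paired-end reads with the reporter assay's full read architecture.

The generator emulates what the sequencer sees after RT-PCR of the reporter
pools:

* sense amplicon = ``UMI (9-11 nt) + umi-anchor + cap-class adapter + UTR +
  common adapter + stagger``, where the stagger is the 0-6 nt prefix the
  library PCR primers add to diversify cluster images;
* mate 2 reads the sense strand (UMI at its 5' end), mate 1 reads the
  antisense strand (stagger Ns, then the 5' anchor that is the reverse
  complement of the common adapter);
* one UMI per cDNA molecule, drawn uniformly; PCR duplicates are i.i.d.
  geometric copies per molecule with a different stagger per copy;
* substitution errors i.i.d. at rate epsilon; no indels, constant qualities.

Read counts per (construct, cap class) are multinomial with weights equal to
the input abundance (input samples) or abundance x true TE (IP samples), so
the ground-truth table drives the IP read composition exactly as translation
efficiency drives immunoprecipitation enrichment in the assay.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .reference import (
    ACAP_ADAPTER,
    COMMON_ADAPTER,
    GCAP_ADAPTER,
    PAIR_5P_ANCHOR,
    ConstructLibrary,
    revcomp,
)

# Fixed 15-nt anchor directly 3' of the UMI in mate 2. It stands in for the
# constant primer-derived sequence between the molecular index and the UTR
# region; the real primer geometry is abstracted behind this constant.
UMI_ANCHOR = "GTCAGTCGGATTCTC"

CAP_CLASSES = ("a_cap", "g_cap")

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadArchitecture:
    """Constants describing where everything sits in a read pair."""

    common_adapter: str = COMMON_ADAPTER
    acap_adapter: str = ACAP_ADAPTER
    gcap_adapter: str = GCAP_ADAPTER
    pair_5p_anchor: str = PAIR_5P_ANCHOR
    umi_anchor: str = UMI_ANCHOR
    read_length: int = 150
    umi_lengths: tuple[int, ...] = (9, 10, 11)
    max_stagger: int = 6

    def __post_init__(self):
        longest = max(
            len(self.common_adapter), len(self.acap_adapter), len(self.gcap_adapter)
        )
        if self.read_length < longest:
            raise ValueError("read_length shorter than the longest adapter")
        if revcomp(self.common_adapter) != self.pair_5p_anchor:
            raise ValueError("pair_5p_anchor must be the reverse complement of the common adapter")

    def cap_adapter(self, cap_class: str) -> str:
        return self.acap_adapter if cap_class == "a_cap" else self.gcap_adapter


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults describe the assay as run: 9-11 nt UMIs with equal weight,
    uniform 0-6 nt stagger, three G-cap spike-ins at 1% of each sample in a
    1:10:100 serial dilution, log-normal input abundances, true log2 TEs
    uniform over (-5, 5) (the assay spans a ~1000-fold TE range), a low
    Illumina-like substitution error rate, and a modest PCR duplication level.
    """

    reads_per_sample: int = 1_000_000
    epsilon: float = 0.001
    te_log2_range: tuple[float, float] = (-5.0, 5.0)
    duplication_mean: float = 1.5
    abundance_sigma: float = 1.0
    spike_ratio: tuple[float, float, float] = (0.01, 0.1, 1.0)
    spike_fraction: float = 0.01
    spike_te: float = 1.0
    umi_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {9: 1 / 3, 10: 1 / 3, 11: 1 / 3}
    )
    fixed_abundance: Mapping[tuple[str, str], float] = field(default_factory=dict)
    fixed_te: Mapping[tuple[str, str], float] = field(default_factory=dict)
    # condition name -> effect; te_scale multiplies the true TE of every
    # non-spike construct whose family is not listed in exempt_families and
    # whose id is not in exempt_ids; te_overrides multiplies per construct id.
    conditions: Mapping[str, Mapping] = field(default_factory=lambda: {"control": {}})

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 0.1:
            raise ValueError("epsilon must be within [0, 0.1]")
        if self.duplication_mean < 1.0:
            raise ValueError("duplication_mean must be >= 1")
        r = self.spike_ratio
        if not (r[0] < r[1] < r[2]):
            raise ValueError("spike_ratio must be strictly increasing")


class SimulationTruth:
    """Ground truth for one simulated experiment.

    Rows are (construct_id, cap_class); spike-ins exist only as G-cap
    molecules. ``te[condition]`` is the IP enrichment factor per row under
    that condition.
    """

    def __init__(
        self,
        construct_ids: list[str],
        cap_classes: list[str],
        input_abundance: np.ndarray,
        te: dict[str, np.ndarray],
        config: SimConfig,
        seed: int,
    ):
        self.construct_ids = construct_ids
        self.cap_classes = cap_classes
        self.input_abundance = input_abundance
        self.te = te
        self.config = config
        self.seed = seed
        if not (len(construct_ids) == len(cap_classes) == len(input_abundance)):
            raise ValueError("truth arrays misaligned")
        if input_abundance.sum() <= 0 or (input_abundance < 0).any():
            raise ValueError("input abundances must be nonnegative with positive total")
        for cond, arr in te.items():
            if (arr <= 0).any():
                raise ValueError(f"true TE must be positive (condition {cond})")

    @property
    def index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.construct_ids, self.cap_classes], names=["construct_id", "cap_class"]
        )

    @property
    def conditions(self) -> list[str]:
        return list(self.te)

    def ip_weights(self, condition: str) -> np.ndarray:
        return self.input_abundance * self.te[condition]

    def expected_log2_te(self, condition: str) -> pd.Series:
        """Exact expectation of the RPM-scale log2 TE estimate.

        RPM normalization is compositional, so every estimate carries the same
        offset -log2(abundance-weighted mean TE); this is the quantity a
        ratio-of-RPMs estimator converges to.
        """
        te = self.te[condition]
        w = self.input_abundance
        offset = np.log2((w * te).sum() / w.sum())
        return pd.Series(np.log2(te) - offset, index=self.index, name="expected_log2_te")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"input_abundance": self.input_abundance}, index=self.index)
        for cond, arr in self.te.items():
            df[f"true_te_{cond}"] = arr
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().reset_index().to_csv(path, sep="\t", index=False)


def build_truth(library: ConstructLibrary, config: SimConfig, seed: int) -> SimulationTruth:
    """Draw a ground-truth table for a library; deterministic given ``seed``.

    Non-spike constructs get one row per cap class with log-normal abundance
    and true TE = 2^Uniform(te_log2_range) unless fixed in the config.
    Spike-ins are G-cap only; their abundances follow the designed dilution
    ratio, scaled so they take ``spike_fraction`` of each sample's molecules.
    """
    if len(library) == 0:
        raise ValueError("library has no constructs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB10]))
    ids, classes, abundance, base_te = [], [], [], []
    lo, hi = config.te_log2_range
    spikes = []
    for rec in library:
        if rec.is_spike_in:
            spikes.append(rec.construct_id)
            continue
        for cls in CAP_CLASSES:
            ids.append(rec.construct_id)
            classes.append(cls)
            key = (rec.construct_id, cls)
            a = config.fixed_abundance.get(key)
            abundance.append(a if a is not None else rng.lognormal(0.0, config.abundance_sigma))
            t = config.fixed_te.get(key)
            base_te.append(t if t is not None else 2.0 ** rng.uniform(lo, hi))
    lib_total = float(np.sum(abundance))
    if spikes:
        ratios = np.asarray(config.spike_ratio, dtype=float)
        if len(spikes) != len(ratios):
            raise ValueError(
                f"library has {len(spikes)} spike-ins but spike_ratio has {len(ratios)} entries"
            )
        f = config.spike_fraction
        scale = (f / (1.0 - f)) * lib_total / ratios.sum() if lib_total > 0 else 1.0
        for sid, r in zip(spikes, ratios):
            ids.append(sid)
            classes.append("g_cap")
            abundance.append(r * scale)
            base_te.append(config.spike_te)
    abundance = np.asarray(abundance, dtype=float)
    base_te = np.asarray(base_te, dtype=float)
    is_spike = np.asarray([c in spikes for c in ids])

    te: dict[str, np.ndarray] = {}
    for cond, effect in config.conditions.items():
        arr = base_te.copy()
        scale = float(effect.get("te_scale", 1.0)) if effect else 1.0
        if scale != 1.0:
            exempt_fam = set(effect.get("exempt_families", ()))
            exempt_ids = set(effect.get("exempt_ids", ()))
            mask = ~is_spike
            if exempt_fam or exempt_ids:
                keep = np.asarray(
                    [
                        (cid in exempt_ids) or (library[cid].family in exempt_fam)
                        for cid in ids
                    ]
                )
                mask &= ~keep
            arr[mask] *= scale
        for cid, s in (effect.get("te_overrides", {}) if effect else {}).items():
            sel = np.asarray([c == cid for c in ids])
            if not sel.any():
                raise ValueError(f"te_overrides names unknown construct {cid!r}")
            arr[sel] *= float(s)
        te[cond] = arr
    return SimulationTruth(ids, classes, abundance, te, config, int(seed))


def _sample_rng(truth: SimulationTruth, sample_id: str) -> np.random.Generator:
    tag = zlib.crc32(sample_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([truth.seed, tag]))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, n)].tobytes().decode()


def generate_read_pairs(
    truth: SimulationTruth,
    library: ConstructLibrary,
    sample_role: str,
    sample_id: str,
    condition: str = "control",
    n_reads: int | None = None,
    arch: ReadArchitecture | None = None,
) -> Iterator[tuple[str, str, str, str, str, str, int]]:
    """Yield ``(read_id, seq1, seq2, construct_id, cap_class, umi, molecule_id)``.

    Deterministic given (truth, sample_id). ``sample_role`` is ``input`` or
    ``IP``; IP composition is abundance x true TE under ``condition``.
    """
    if sample_role not in ("input", "IP"):
        raise ValueError(f"sample_role must be 'input' or 'IP', got {sample_role!r}")
    if condition not in truth.te:
        raise ValueError(f"condition {condition!r} not in truth ({list(truth.te)})")
    arch = arch or ReadArchitecture()
    cfg = truth.config
    for cid in truth.construct_ids:
        if cid not in library:
            raise ValueError(f"truth construct {cid!r} missing from library")
    rng = _sample_rng(truth, sample_id)
    n_reads = int(n_reads if n_reads is not None else cfg.reads_per_sample)
    n_mol = max(1, round(n_reads / cfg.duplication_mean))
    w = truth.input_abundance if sample_role == "input" else truth.ip_weights(condition)
    if w.sum() <= 0:
        raise ValueError("sampling weights sum to zero")
    mol_counts = rng.multinomial(n_mol, w / w.sum())

    umi_lens = np.asarray(sorted(cfg.umi_length_weights), dtype=int)
    umi_w = np.asarray([cfg.umi_length_weights[k] for k in umi_lens], dtype=float)
    umi_w = umi_w / umi_w.sum()
    p_dup = 1.0 / cfg.duplication_mean
    eps = cfg.epsilon
    rl = arch.read_length
    serial = 0

    # Pre-drawn error counts, thinned per read for reads shorter than rl:
    # Binomial(rl, eps) with positions uniform on [0, rl) restricted to the
    # read is exactly Binomial(len, eps).
    def mutate(seq: str) -> str:
        if eps == 0.0:
            return seq
        k = int(rng.binomial(rl, eps))
        if k == 0:
            return seq
        pos = rng.integers(0, rl, k)
        chars = list(seq)
        n = len(chars)
        for p in pos:
            if p >= n or chars[p] == "N":
                continue
            chars[p] = "ACGT"[(("ACGT".index(chars[p])) + int(rng.integers(1, 4))) % 4]
        return "".join(chars)

    for row, m in enumerate(mol_counts):
        if m == 0:
            continue
        cid = truth.construct_ids[row]
        cls = truth.cap_classes[row]
        core = (
            arch.umi_anchor
            + arch.cap_adapter(cls)
            + library.class_sequence(cid, cls)
            + arch.common_adapter
        )
        lens = umi_lens[rng.choice(len(umi_lens), size=m, p=umi_w)]
        bases = _random_bases(rng, int(lens.sum()))
        copies = rng.geometric(p_dup, size=m)
        staggers = rng.integers(0, arch.max_stagger + 1, size=int(copies.sum()))
        off = 0
        ri = 0
        for mi in range(m):
            ul = int(lens[mi])
            umi = bases[off : off + ul]
            off += ul
            mol_id = serial
            sense_body = umi + core
            for _ in range(int(copies[mi])):
                st = int(staggers[ri])
                ri += 1
                sense = sense_body + "N" * st
                seq2 = sense[:rl]
                seq1 = revcomp(sense)[:rl]
                rid = f"{sample_id}.{serial}"
                serial += 1
                yield rid, mutate(seq1), mutate(seq2), cid, cls, umi, mol_id


def stream_read_pairs(*args, **kwargs) -> Iterator[tuple[str, str, str]]:
    """Like :func:`generate_read_pairs` but yielding only (read_id, seq1, seq2),
    the shape :func:`iresmpra.readproc.process_pairs` consumes."""
    for rid, s1, s2, *_ in generate_read_pairs(*args, **kwargs):
        yield rid, s1, s2


def random_library(
    n_candidates: int,
    utr_length: int = 150,
    seed: int = 0,
    candidate_group: str = "simulated",
) -> ConstructLibrary:
    """A synthetic construct library with the assay's control layout.

    ``n_candidates`` random candidate UTRs plus named positive controls
    (HCV, CrPV), three scramble negatives and the three G-cap spike-ins —
    all with random sequences (this is a simulation library: ids mirror the
    control roles, sequences do not reproduce the real elements).
    """
    from .reference import ConstructRecord

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11B]))
    records = []

    def seq() -> str:
        return _random_bases(rng, utr_length)

    records.append(ConstructRecord("HCV", seq(), "positive_control"))
    records.append(ConstructRecord("CrPV", seq(), "positive_control"))
    for i in range(1, 4):
        records.append(ConstructRecord(f"scramble{i}", seq(), "negative_control"))
    for i in range(n_candidates):
        records.append(
            ConstructRecord(f"cand{i:04d}", seq(), f"candidate:{candidate_group}")
        )
    for i in range(1, 4):
        records.append(ConstructRecord(f"spike{i}", seq(), "spike_in"))
    return ConstructLibrary(records)


def make_sample_sheet(
    conditions: list[str],
    n_bio_rep: int = 1,
    n_tech_rep: int = 1,
    fastq_dir: str = ".",
) -> pd.DataFrame:
    """Sample sheet for a simulated experiment (input + IP per replicate)."""
    rows = []
    for cond in conditions:
        for role in ("input", "IP"):
            for b in range(1, n_bio_rep + 1):
                for t in range(1, n_tech_rep + 1):
                    sid = f"{role}_{cond}_b{b}_t{t}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "fastq_r1": f"{fastq_dir}/{sid}_R1.fastq",
                            "fastq_r2": f"{fastq_dir}/{sid}_R2.fastq",
                            "role": role,
                            "condition": cond,
                            "bio_rep": str(b),
                            "tech_rep": str(t),
                        }
                    )
    return pd.DataFrame(rows)


def _open_text(path, mode="wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


def simulate_reads(
    truth: SimulationTruth,
    library: ConstructLibrary,
    sample_role: str,
    out_r1,
    out_r2,
    sample_id: str | None = None,
    condition: str = "control",
    n_reads: int | None = None,
    arch: ReadArchitecture | None = None,
    sidecar=None,
) -> int:
    """Write a FASTQ pair (Phred+33, constant quality) plus an optional
    per-read truth sidecar TSV. Returns the number of read pairs written.

    Output is bit-identical for identical (truth, sample_id, parameters).
    """
    sample_id = sample_id or f"{sample_role}_{condition}"
    n = 0
    side = open(sidecar, "w") if sidecar else None
    if side:
        side.write("read_id\tconstruct_id\tcap_class\tumi\tmolecule_id\n")
    with _open_text(out_r1) as f1, _open_text(out_r2) as f2:
        buf1, buf2 = [], []
        for rid, s1, s2, cid, cls, umi, mol in generate_read_pairs(
            truth, library, sample_role, sample_id, condition, n_reads, arch
        ):
            buf1.append(f"@{rid}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            buf2.append(f"@{rid}/2\n{s2}\n+\n{'I' * len(s2)}\n")
            if side:
                side.write(f"{rid}\t{cid}\t{cls}\t{umi}\t{mol}\n")
            n += 1
            if len(buf1) >= 20000:
                f1.write("".join(buf1))
                f2.write("".join(buf2))
                buf1, buf2 = [], []
        f1.write("".join(buf1))
        f2.write("".join(buf2))
    if side:
        side.close()
    return n
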