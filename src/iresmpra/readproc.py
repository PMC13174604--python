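"""Raw read pairs -> unique-UMI counts per (construct, cap class, sample).

Stages, mirroring the assay's data processing:

1. UMI / stagger extraction. The UMI is the 9-11 bases 5' of a fixed anchor on
   the reporter-side mate; the stagger is the 0-6 leading bases before the 5'
   anchor on mate 1. Reads whose anchors cannot be located are excluded.
2. Overlap merging of each pair into a single read where the insert is short
   enough (consensus toward the first read given).
3. Cap-class splitting: merged reads are assigned a_cap / g_cap by their
   17-nt cap-class adapter after removal of the common adapter (exact match
   by default); unmerged pairs use the 5' anchor on mate 1 plus the cap
   adapter on mate 2 with a floor(0.07 x length) mismatch budget per adapter.
4. Stage-one duplicate collapse on (insert, UMI, stagger): PCR duplicates that
   differ only in library stagger survive this stage by design.
5. Assignment to the construct database by exact / near-exact ungapped
   matching (k-mer seed lookup + Hamming verification); best-hit ties are
   ambiguous and discarded, never broken.
6. Stage-two collapse: counts are the number of distinct UMIs per
   (construct, cap class, sample).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import ConstructLibrary, revcomp
from .simulate import ReadArchitecture

logger = logging.getLogger(__name__)

# assignment sentinels (never valid construct ids)
AMBIGUOUS = "<ambiguous>"
UNASSIGNED = "<unassigned>"

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "fastq_r1",
    "fastq_r2",
    "role",
    "condition",
    "bio_rep",
    "tech_rep",
]


@dataclass(slots=True)
class ProcessedRead:
    """One read (pair) after UMI extraction, merging and cap-class splitting."""

    read_id: str
    insert: str | None
    cap_class: str  # a_cap | g_cap | unassigned
    umi: str | None
    stagger_len: int | None
    merged: bool
    partial: bool = False  # unmerged pair: insert is a 5' prefix of the UTR


@dataclass(frozen=True)
class ReadProcParams:
    """Tunable knobs of the read-processing stage (defaults as the assay ran)."""

    min_overlap: int = 10
    max_mismatch_rate: float = 0.1
    max_mismatches: int = 2  # construct assignment budget
    error_rate_single: float = 0.0  # adapter mismatch rate, merged reads
    error_rate_paired: float = 0.07  # adapter mismatch rate, unmerged pairs
    anchor_max_mm: int = 1  # UMI/stagger anchor tolerance
    min_partial_insert: int = 30  # shortest prefix worth assigning


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, with optional early exit."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    if a == b:
        return 0
    d = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                d += 1
        return d
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def find_approx(seq: str, pattern: str, max_mm: int = 0, start: int = 0) -> int:
    """Leftmost position of ``pattern`` in ``seq`` with <= max_mm mismatches (-1 if absent)."""
    if max_mm == 0:
        return seq.find(pattern, start)
    m = len(pattern)
    for i in range(start, len(seq) - m + 1):
        if hamming(seq[i : i + m], pattern, max_mm) <= max_mm:
            return i
    return -1


def _overlap_mismatches(r1: str, rc2: str, d: int, limit: int) -> tuple[int, int]:
    """Overlap length and mismatch count (early exit) for rc2 placed at offset d of r1."""
    a = max(0, d)
    b = min(len(r1), d + len(rc2))
    ov = b - a
    if ov <= 0:
        return 0, limit + 1
    mm = 0
    seg1 = r1[a:b]
    seg2 = rc2[a - d : b - d]
    if seg1 != seg2:
        for x, y in zip(seg1, seg2):
            if x != y:
                mm += 1
                if mm > limit:
                    break
    return ov, mm


def merge_pairs(
    r1: str,
    r2: str,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> str | None:
    """Merge a pair by its best ungapped overlap, or return None if unmergeable.

    The best overlap of ``r1`` with the reverse complement of ``r2`` is the
    one with the lowest mismatch fraction (ties: longest overlap, then
    leftmost placement). Pairs whose best overlap is shorter than
    ``min_overlap`` or exceeds ``max_mismatch_rate`` stay unmerged.
    Disagreements in the overlap are resolved toward ``r1``'s base.

    Exact seed probes locate the overlap in O(n) for the typical read; the
    exhaustive offset scan only runs when no probe anchors.
    """
    rc2 = revcomp(r2)
    n1, n2 = len(r1), len(rc2)
    candidates: set[int] = set()
    probe_len = 20 if min(n1, n2) >= 20 else max(min_overlap, min(n1, n2))
    for off in (0, 25, 50):
        probe = rc2[off : off + probe_len]
        if len(probe) < probe_len:
            break
        j = r1.find(probe)
        while j != -1:
            candidates.add(j - off)
            j = r1.find(probe, j + 1)
    tail = r1[-probe_len:]
    j = rc2.find(tail)
    while j != -1:
        candidates.add(n1 - probe_len - j)
        j = rc2.find(tail, j + 1)

    def best_of(ds) -> tuple | None:
        best = None
        for d in ds:
            ov = min(n1, d + n2) - max(0, d)
            if ov < min_overlap:
                continue
            limit = int(max_mismatch_rate * ov)
            ov, mm = _overlap_mismatches(r1, rc2, d, limit)
            if mm > limit:
                continue
            key = (mm / ov, -ov, d)
            if best is None or key < best[0]:
                best = (key, d, ov)
        return best

    best = best_of(sorted(candidates))
    if best is None:
        # exhaustive scan over every admissible relative placement
        best = best_of(range(-(n2 - min_overlap), n1 - min_overlap + 1))
        if best is None:
            return None
    d = best[1]
    left = rc2[: -d] if d < 0 else ""
    right = rc2[n1 - d :] if d + n2 > n1 else ""
    return left + r1 + right


def extract_umi_and_stagger(
    r1: str,
    r2: str,
    arch: ReadArchitecture | None = None,
    max_mm: int = 1,
) -> tuple[str | None, int | None, tuple[str, str]]:
    """Locate the UMI and the library stagger; return them plus trimmed mates.

    The UMI is the 9-11 nt 5' of the fixed anchor on the reporter-side mate
    (length disambiguated by the anchor offset); the stagger is the number of
    leading bases on mate 1 before the pair 5' anchor, in 0-6. A missing
    anchor yields ``None`` for that field and the corresponding mate is left
    untrimmed (such reads are excluded from counting downstream).
    """
    arch = arch or ReadArchitecture()
    p5 = arch.pair_5p_anchor
    np5 = len(p5)
    stagger = None
    for s in range(arch.max_stagger + 1):
        if r1.startswith(p5, s):
            stagger = s
            break
    if stagger is None and max_mm > 0:
        for s in range(arch.max_stagger + 1):
            seg = r1[s : s + np5]
            if len(seg) == np5 and hamming(seg, p5, max_mm) <= max_mm:
                stagger = s
                break
    ua = arch.umi_anchor
    nua = len(ua)
    umi = None
    m2t = r2
    for ul in arch.umi_lengths:
        if r2.startswith(ua, ul):
            umi = r2[:ul]
            m2t = r2[ul + nua :]
            break
    else:
        if max_mm > 0:
            for ul in arch.umi_lengths:
                seg = r2[ul : ul + nua]
                if len(seg) == nua and hamming(seg, ua, max_mm) <= max_mm:
                    umi = r2[:ul]
                    m2t = r2[ul + nua :]
                    break
    m1t = r1[stagger:] if stagger is not None else r1
    return umi, stagger, (m1t, m2t)


def split_cap_classes(
    read: str | tuple[str, str],
    arch: ReadArchitecture | None = None,
    mode: str = "single",
    error_rate_single: float = 0.0,
    error_rate_paired: float = 0.07,
) -> tuple[str, str | None, bool]:
    """Classify a merged read or trimmed pair as a_cap / g_cap / unassigned.

    Returns ``(cap_class, insert, partial)``. ``unassigned`` is a value, not
    an error: it covers reads matching neither cap adapter, reads matching
    both (conservatively discarded), and merged reads lacking the common
    adapter. ``partial`` marks unmerged pairs whose insert is only the 5'
    prefix of the UTR (the common adapter was out of reach of mate 2).

    Single mode removes the common adapter with a mismatch budget of
    ``floor(error_rate_single x len)`` (0 by default, i.e. exact), then
    searches for either cap-class adapter under the same rule. Paired mode
    requires the pair 5' anchor on mate 1 and a cap-class adapter at the
    start of mate 2, each within ``floor(0.07 x len)`` mismatches.
    """
    arch = arch or ReadArchitecture()
    acap, gcap, common = arch.acap_adapter, arch.gcap_adapter, arch.common_adapter
    if mode == "single":
        assert isinstance(read, str)
        b_common = int(error_rate_single * len(common))
        b_cap = int(error_rate_single * len(acap))
        pc = find_approx(read, common, b_common)
        if pc == -1:
            return "unassigned", None, False
        left = read[:pc]
        pa = find_approx(left, acap, b_cap)
        pg = find_approx(left, gcap, b_cap)
        if (pa == -1) == (pg == -1):  # neither, or both
            return "unassigned", None, False
        if pa != -1:
            cls, pos = "a_cap", pa
        else:
            cls, pos = "g_cap", pg
        insert = left[pos + len(acap) :]
        if not insert:
            return "unassigned", None, False
        return cls, insert, False
    if mode != "paired":
        raise ValueError(f"mode must be 'single' or 'paired', got {mode!r}")
    m1t, m2t = read
    p5 = arch.pair_5p_anchor
    if len(m1t) < len(p5) or hamming(m1t[: len(p5)], p5, int(0.07 * len(p5))) > int(
        0.07 * len(p5)
    ):
        return "unassigned", None, False
    b_cap = int(error_rate_paired * len(acap))
    if len(m2t) < len(acap):
        return "unassigned", None, False
    head = m2t[: len(acap)]
    hit_a = hamming(head, acap, b_cap) <= b_cap
    hit_g = hamming(head, gcap, b_cap) <= b_cap
    if hit_a == hit_g:
        return "unassigned", None, False
    cls = "a_cap" if hit_a else "g_cap"
    insert = m2t[len(acap) :]
    pc = find_approx(insert, common, int(error_rate_paired * len(common)))
    partial = pc == -1
    if not partial:
        insert = insert[:pc]
    if not insert:
        return "unassigned", None, False
    return cls, insert, partial


def precollapse_duplicates(reads: Iterable[ProcessedRead]) -> list[ProcessedRead]:
    """Stage-one collapse: one representative per (insert, cap class, UMI, stagger).

    Sequence duplicates that differ only in library stagger length are
    retained separately at this stage; the stage-two unique-UMI count removes
    them once reads are assigned to constructs. The cap class is part of the
    key because the class adapters are already trimmed from the insert.
    """
    seen: set[tuple] = set()
    out = []
    for r in reads:
        key = (r.insert, r.cap_class, r.umi, r.stagger_len)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


class ConstructMatcher:
    """Exact / near-exact ungapped matcher against the construct database.

    A read insert is compared against the expected cap-class sequence of every
    candidate construct (the UTR, with the internal A-cap barcode for a_cap
    reads when the library defines one). Candidates are found by exact
    position-anchored k-mer seeds, then verified by Hamming distance with a
    hard ``max_mismatches`` budget. Two or more equally good best hits are
    ambiguous; no hit within budget is unassigned — both are excluded from
    counting, never rescued by tie-breaking.
    """

    SEED_K = 15

    def __init__(self, library: ConstructLibrary, max_mismatches: int = 2):
        self.library = library
        self.max_mismatches = max_mismatches
        self._exact: dict[str, dict[str, str]] = {}
        self._seeds: dict[str, dict[tuple[int, str], set[str]]] = {}
        self._seqs: dict[str, dict[str, str]] = {}
        k = self.SEED_K
        for cls in ("a_cap", "g_cap"):
            exact: dict[str, str] = {}
            seeds: dict[tuple[int, str], set[str]] = {}
            seqs: dict[str, str] = {}
            for rec in library:
                cid = rec.construct_id
                seq = library.class_sequence(cid, cls)
                seqs[cid] = seq
                if seq in exact:
                    exact[seq] = AMBIGUOUS
                else:
                    exact[seq] = cid
                for pos in range(0, len(seq) - k + 1, k):
                    seeds.setdefault((pos, seq[pos : pos + k]), set()).add(cid)
            self._exact[cls] = exact
            self._seeds[cls] = seeds
            self._seqs[cls] = seqs

    def assign(self, insert: str, cap_class: str, partial: bool = False) -> str:
        exact = self._exact[cap_class]
        if not partial:
            hit = exact.get(insert)
            if hit is not None:
                return hit
        k = self.SEED_K
        seeds = self._seeds[cap_class]
        cand: set[str] = set()
        for pos in range(0, len(insert) - k + 1, k):
            s = seeds.get((pos, insert[pos : pos + k]))
            if s:
                cand |= s
        if not cand:
            # short inserts cannot carry enough intact seeds — fall back to a
            # full scan, which is cheap at these lengths
            if len(insert) < (self.max_mismatches + 1) * k:
                cand = set(self._seqs[cap_class])
            else:
                return UNASSIGNED
        seqs = self._seqs[cap_class]
        n = len(insert)
        best_d = self.max_mismatches + 1
        best_id = UNASSIGNED
        tied = False
        for cid in cand:
            ref = seqs[cid]
            if partial:
                if len(ref) < n:
                    continue
                ref = ref[:n]
            elif len(ref) != n:
                continue
            d = hamming(insert, ref, best_d)
            if d < best_d:
                best_d, best_id, tied = d, cid, False
            elif d == best_d and d <= self.max_mismatches and cid != best_id:
                tied = True
        if best_d > self.max_mismatches:
            return UNASSIGNED
        return AMBIGUOUS if tied else best_id


def assign_to_construct(
    insert: str,
    library: ConstructLibrary,
    max_mismatches: int = 2,
    cap_class: str = "g_cap",
    partial: bool = False,
) -> str:
    """Assign one insert to a construct (see :class:`ConstructMatcher`).

    Returns the construct id, or the ``AMBIGUOUS`` / ``UNASSIGNED`` sentinel.
    """
    matcher = library._matchers.get(max_mismatches)
    if matcher is None:
        matcher = ConstructMatcher(library, max_mismatches)
        library._matchers[max_mismatches] = matcher
    return matcher.assign(insert, cap_class, partial)


def count_unique_umis(
    assigned: Iterable[tuple[str, str, str]], sample_id: str
) -> pd.DataFrame:
    """Distinct-UMI counts per (construct, cap class) for one sample.

    Input is an iterable of ``(construct_id, cap_class, umi)``; the same UMI
    seen on two different constructs counts once for each.
    """
    sets: dict[tuple[str, str], set[str]] = {}
    for cid, cls, umi in assigned:
        sets.setdefault((cid, cls), set()).add(umi)
    rows = [
        {"construct_id": cid, "cap_class": cls, "sample_id": sample_id, "count": len(s)}
        for (cid, cls), s in sorted(sets.items())
    ]
    return pd.DataFrame(rows, columns=["construct_id", "cap_class", "sample_id", "count"])


@dataclass
class SampleProcessResult:
    sample_id: str
    counts: pd.DataFrame  # construct_id, cap_class, sample_id, count
    report: dict
    assignments: dict[str, tuple[str, str]] | None = None  # read_id -> (cap_class, cid)


def process_pairs(
    pairs: Iterable[tuple[str, str, str]],
    library: ConstructLibrary,
    sample_id: str,
    arch: ReadArchitecture | None = None,
    params: ReadProcParams | None = None,
    collect_assignments: bool = False,
) -> SampleProcessResult:
    """Run the full per-sample read-processing pipeline on (id, r1, r2) triples.

    Streaming: reads are never materialised; stage-one collapse and the
    unique-UMI count are kept as hash sets. Construct assignment is memoised
    per distinct insert, which makes the matcher cost negligible next to
    string handling.
    """
    arch = arch or ReadArchitecture()
    params = params or ReadProcParams()
    matcher = library._matchers.get(params.max_mismatches)
    if matcher is None:
        matcher = ConstructMatcher(library, params.max_mismatches)
        library._matchers[params.max_mismatches] = matcher

    p5 = arch.pair_5p_anchor
    ua = arch.umi_anchor
    np5, nua = len(p5), len(ua)
    umi_lengths = arch.umi_lengths
    max_st = arch.max_stagger
    anchor_mm = params.anchor_max_mm
    min_ov = params.min_overlap
    mm_rate = params.max_mismatch_rate

    n_total = n_umi_missing = n_merged = n_unmerged = 0
    class_counts = {"a_cap": 0, "g_cap": 0, "unassigned": 0}
    n_ambiguous = n_unassigned_construct = n_counted = 0

    seen: set[tuple] = set()
    insert_pool: dict[str, str] = {}
    assign_memo: dict[tuple, str] = {}
    umi_sets: dict[tuple[str, str], set[str]] = {}
    assignments: dict[str, tuple[str, str]] | None = {} if collect_assignments else None

    for rid, r1, r2 in pairs:
        n_total += 1
        # --- stagger (mate 1) ---
        st = None
        for s in range(max_st + 1):
            if r1.startswith(p5, s):
                st = s
                break
        if st is None and anchor_mm:
            for s in range(max_st + 1):
                seg = r1[s : s + np5]
                if len(seg) == np5 and hamming(seg, p5, anchor_mm) <= anchor_mm:
                    st = s
                    break
        # --- UMI (mate 2) ---
        umi = None
        for ul in umi_lengths:
            if r2.startswith(ua, ul):
                umi = r2[:ul]
                break
        if umi is None and anchor_mm:
            for ul in umi_lengths:
                seg = r2[ul : ul + nua]
                if len(seg) == nua and hamming(seg, ua, anchor_mm) <= anchor_mm:
                    umi = r2[:ul]
                    break
        if umi is None or st is None:
            n_umi_missing += 1
            class_counts["unassigned"] += 1
            if assignments is not None:
                assignments[rid] = ("unassigned", UNASSIGNED)
            continue
        m1t = r1[st:]
        m2t = r2[len(umi) + nua :]
        # --- merge ---
        merged = merge_pairs(m2t, m1t, min_ov, mm_rate)
        if merged is not None:
            n_merged += 1
            cls, insert, partial = split_cap_classes(
                merged, arch, "single", params.error_rate_single, params.error_rate_paired
            )
        else:
            n_unmerged += 1
            cls, insert, partial = split_cap_classes(
                (m1t, m2t), arch, "paired", params.error_rate_single, params.error_rate_paired
            )
        class_counts[cls if insert is not None else "unassigned"] += 1
        if insert is None:
            if assignments is not None:
                assignments[rid] = ("unassigned", UNASSIGNED)
            continue
        insert = insert_pool.setdefault(insert, insert)
        # cap class is part of the collapse key: with the adapters trimmed,
        # a_cap and g_cap molecules of one construct can share the insert
        key = (insert, cls, umi, st)
        memo_key = (insert, cls, partial)
        if key in seen:
            if assignments is not None:
                assignments[rid] = (cls, assign_memo.get(memo_key, UNASSIGNED))
            continue
        seen.add(key)
        cid = assign_memo.get(memo_key)
        if cid is None:
            if partial and len(insert) < params.min_partial_insert:
                cid = UNASSIGNED
            else:
                cid = matcher.assign(insert, cls, partial)
            assign_memo[memo_key] = cid
        if assignments is not None:
            assignments[rid] = (cls, cid)
        if cid == AMBIGUOUS:
            n_ambiguous += 1
            continue
        if cid == UNASSIGNED:
            n_unassigned_construct += 1
            continue
        umi_sets.setdefault((cid, cls), set()).add(umi)
        n_counted += 1

    rows = [
        {"construct_id": cid, "cap_class": cls, "sample_id": sample_id, "count": len(s)}
        for (cid, cls), s in sorted(umi_sets.items())
    ]
    counts = pd.DataFrame(rows, columns=["construct_id", "cap_class", "sample_id", "count"])
    report = {
        "sample_id": sample_id,
        "total": n_total,
        "umi_or_stagger_missing": n_umi_missing,
        "merged": n_merged,
        "unmerged": n_unmerged,
        "a_cap": class_counts["a_cap"],
        "g_cap": class_counts["g_cap"],
        "unassigned": class_counts["unassigned"],
        "ambiguous": n_ambiguous,
        "unassigned_construct": n_unassigned_construct,
        "counted_reads": n_counted,
    }
    return SampleProcessResult(sample_id, counts, report, assignments)


def iterate_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, seq1, seq2) from a FASTQ pair (gzip ok); IDs must agree."""

    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    def _stem(title: str) -> str:
        rid = title.split()[0]
        return rid[:-2] if rid.endswith(("/1", "/2")) else rid

    with _open(r1_path) as f1, _open(r2_path) as f2:
        it2 = FastqGeneralIterator(f2)
        for t1, s1, _ in FastqGeneralIterator(f1):
            try:
                t2, s2, _ = next(it2)
            except StopIteration:
                raise ValueError(f"{r2_path} has fewer reads than {r1_path}") from None
            rid = _stem(t1)
            if rid != _stem(t2):
                raise ValueError(f"mate ID mismatch: {t1!r} vs {t2!r}")
            yield rid, s1, s2
        if next(it2, None) is not None:
            raise ValueError(f"{r2_path} has more reads than {r1_path}")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate the sample sheet TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in sample sheet: {dups}")
    bad_role = set(df["role"]) - {"input", "IP"}
    if bad_role:
        raise ValueError(f"sample sheet roles must be input/IP, got {sorted(bad_role)}")
    return df


def process_samplesheet(
    sheet: pd.DataFrame,
    library: ConstructLibrary,
    arch: ReadArchitecture | None = None,
    params: ReadProcParams | None = None,
):
    """Process every sample in a sheet; returns (CountMatrix, report DataFrame)."""
    from .quant import CountMatrix  # local import: quant depends on this module

    results = []
    for row in sheet.itertuples(index=False):
        pairs = iterate_fastq_pairs(row.fastq_r1, row.fastq_r2)
        res = process_pairs(pairs, library, row.sample_id, arch, params)
        logger.info(
            "processed %s: %d reads, %d a_cap, %d g_cap, %d unassigned",
            row.sample_id,
            res.report["total"],
            res.report["a_cap"],
            res.report["g_cap"],
            res.report["unassigned"],
        )
        results.append(res)
    counts = pd.concat([r.counts for r in results], ignore_index=True)
    samples = sheet[["sample_id", "role", "condition", "bio_rep", "tech_rep"]].copy()
    reports = pd.DataFrame([r.report for r in results])
    return CountMatrix(counts, samples), reports
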