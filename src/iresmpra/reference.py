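"""Reporter construct library: records, FASTA I/O, and variant-library design rules.

A construct is one 5'UTR variant cloned upstream of the tagged reporter. The same
UTR is transcribed twice — once with a functional m7G cap (G-cap, measuring
cap-dependent initiation) and once with a non-functional A-cap followed by a
stable stemloop (A-cap, measuring IRES activity). The two pools are told apart in
sequencing by a pair of 17-nt cap-class adapters directly 5' of the UTR.

Coordinates are 1-based closed intervals throughout. The internal alphabet is DNA
(A/C/G/T); RNA input is accepted and U is mapped to T at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

# Adapter constants shared by the whole package. The two cap-class adapters both
# end in the HindIII half-site that joins them to the UTR; the common adapter is
# the BglII-side junction into the reporter CDS. PAIR_5P_ANCHOR is the reverse
# complement of COMMON_ADAPTER, i.e. the same junction read from the antisense
# mate.
COMMON_ADAPTER = "AGATCTGTGATTAAG"
ACAP_ADAPTER = "AGTCCGCATCCAAGCTT"
GCAP_ADAPTER = "TCCAAGCGATCAAGCTT"
PAIR_5P_ANCHOR = "CTTAATCACAGATCT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# transversions that ablate base pairing while preserving composition class
_TRANSVERSION = str.maketrans("ACGT", "CATG")

VALID_FAMILIES = ("positive_control", "negative_control", "spike_in")

_ALPHABET_RE = re.compile(r"^[ACGT]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Per-position complement without strand reversal."""
    return seq.translate(_COMPLEMENT)


def transversion_swap(seq: str) -> str:
    """Pairing-ablating transversion map A<->C, G<->T (an involution)."""
    return seq.translate(_TRANSVERSION)


def _normalize_sequence(seq: str, context: str) -> str:
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError(f"empty sequence for {context}")
    if not _ALPHABET_RE.match(s):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(
            f"sequence for {context} contains characters outside A/C/G/T(/U): {bad}"
        )
    return s


def _validate_family(family: str) -> str:
    if family in VALID_FAMILIES or family.startswith("candidate:"):
        return family
    raise ValueError(
        f"unknown family {family!r}; expected one of {VALID_FAMILIES} or 'candidate:<group>'"
    )


@dataclass(frozen=True)
class ConstructRecord:
    """One reporter 5'UTR variant.

    Parameters
    ----------
    construct_id : unique identifier within a library.
    utr_sequence : DNA sequence of the 5'UTR insert (uppercase A/C/G/T).
    family : role label — ``positive_control``, ``negative_control``,
        ``spike_in`` or ``candidate:<group>``.
    structure_id : optional reference to a secondary structure record.
    """

    construct_id: str
    utr_sequence: str
    family: str = "candidate:unlabeled"
    structure_id: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "utr_sequence", _normalize_sequence(self.utr_sequence, self.construct_id)
        )
        _validate_family(self.family)
        if not self.construct_id:
            raise ValueError("construct_id must be non-empty")

    @property
    def is_spike_in(self) -> bool:
        return self.family == "spike_in"


@dataclass(frozen=True)
class PairedRegion:
    """A base-paired helix or pseudoknot stem on a wildtype sequence.

    ``left`` and ``right`` are 1-based closed intervals; ``left`` is strictly
    upstream of ``right`` and both have the same length (positions pair up
    left[i] with right[-1-i] in the folded helix, but mutation design only
    needs the intervals).
    """

    name: str
    left: tuple[int, int]
    right: tuple[int, int]

    def __post_init__(self):
        (i, j), (k, l) = self.left, self.right
        if not (1 <= i <= j):
            raise ValueError(f"region {self.name}: bad left interval {self.left}")
        if not (k <= l):
            raise ValueError(f"region {self.name}: bad right interval {self.right}")
        if j >= k:
            raise ValueError(
                f"region {self.name}: left interval must end strictly before right starts"
            )
        if (j - i) != (l - k):
            raise ValueError(f"region {self.name}: interval lengths differ")


class ConstructLibrary:
    """Ordered collection of constructs plus the cap-class barcode pair.

    ``acap_barcode``/``gcap_barcode`` are the 17-nt adapters that distinguish
    A-cap from G-cap reads; ``acap_internal_barcode`` is an optional extra tag
    inserted inside A-cap UTRs (empty by default, in which case the adapters
    alone carry the class information).
    """

    def __init__(
        self,
        constructs: Iterable[ConstructRecord],
        acap_barcode: str = ACAP_ADAPTER,
        gcap_barcode: str = GCAP_ADAPTER,
        common_adapter: str = COMMON_ADAPTER,
        acap_internal_barcode: str = "",
        acap_internal_offset: int = 0,
    ):
        self.constructs: list[ConstructRecord] = list(constructs)
        if not self.constructs:
            raise ValueError("a construct library must contain at least one construct")
        self._by_id: dict[str, ConstructRecord] = {}
        for rec in self.constructs:
            if rec.construct_id in self._by_id:
                raise ValueError(f"duplicate construct_id: {rec.construct_id!r}")
            self._by_id[rec.construct_id] = rec
        if acap_barcode == gcap_barcode:
            raise ValueError("A-cap and G-cap barcodes must differ")
        if len(acap_barcode) != len(gcap_barcode):
            raise ValueError("A-cap and G-cap barcodes must have the same length")
        self.acap_barcode = _normalize_sequence(acap_barcode, "acap_barcode")
        self.gcap_barcode = _normalize_sequence(gcap_barcode, "gcap_barcode")
        self.common_adapter = _normalize_sequence(common_adapter, "common_adapter")
        self.acap_internal_barcode = (
            _normalize_sequence(acap_internal_barcode, "acap_internal_barcode")
            if acap_internal_barcode
            else ""
        )
        self.acap_internal_offset = acap_internal_offset
        self._matchers: dict = {}  # cache used by readproc.ConstructMatcher

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    def __contains__(self, construct_id: str) -> bool:
        return construct_id in self._by_id

    def __getitem__(self, construct_id: str) -> ConstructRecord:
        return self._by_id[construct_id]

    @property
    def ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    @property
    def spike_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs if c.is_spike_in]

    def class_sequence(self, construct_id: str, cap_class: str) -> str:
        """Expected UTR-insert sequence for one cap class.

        A-cap copies carry the optional internal barcode; G-cap copies are the
        plain UTR.
        """
        utr = self._by_id[construct_id].utr_sequence
        if cap_class == "a_cap" and self.acap_internal_barcode:
            return attach_acap_barcode(
                utr, self.acap_internal_barcode, self.acap_internal_offset
            )
        return utr


def load_constructs(fasta_path, **library_kwargs) -> ConstructLibrary:
    """Read a construct library from FASTA.

    Record IDs may carry a family tag either as an ``|family=<tag>`` suffix on
    the ID or as a ``family=<tag>`` token in the description; untagged records
    default to ``candidate:unlabeled``. Sequences are uppercased and U→T.
    Duplicate IDs, empty sequences and non-ACGT/U characters are hard errors.
    """
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        cid = rec.id
        family = "candidate:unlabeled"
        if "|family=" in cid:
            cid, _, family = cid.rpartition("|family=")
        else:
            m = re.search(r"(?:^|\s)family=(\S+)", rec.description)
            if m:
                family = m.group(1)
        records.append(ConstructRecord(cid, str(rec.seq), family=family))
    return ConstructLibrary(records, **library_kwargs)


def write_constructs(library: ConstructLibrary, path, width: int = 80) -> None:
    """Write a library as FASTA with ``><id> family=<tag>`` headers."""
    with open(path, "w") as fh:
        for rec in library:
            fh.write(f">{rec.construct_id} family={rec.family}\n")
            seq = rec.utr_sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def attach_acap_barcode(utr: str, barcode: str, offset: int) -> str:
    """Insert the A-cap identification barcode into a UTR at ``offset`` (0-based)."""
    if not 0 <= offset <= len(utr):
        raise ValueError(f"barcode offset {offset} outside [0, {len(utr)}]")
    return utr[:offset] + barcode + utr[offset:]


_WINDOW_ID_RE = re.compile(r"_m(\d+)-(\d+)$")


def parse_window_id(construct_id: str) -> tuple[int, int]:
    """Recover the 1-based window ``(start, end)`` encoded in a scanning-variant ID."""
    m = _WINDOW_ID_RE.search(construct_id)
    if not m:
        raise ValueError(f"{construct_id!r} does not encode a scanning window")
    return int(m.group(1)), int(m.group(2))


def design_scanning_mutants(
    wildtype: str,
    window: int,
    step: int,
    rule: str,
    wildtype_id: str = "WT",
    family: str | None = None,
) -> list[ConstructRecord]:
    """Scanning mutagenesis across a wildtype sequence.

    One variant per window start ``s ∈ {1, 1+step, ...}`` with
    ``s+window-1 <= len(wildtype)``. ``rule='replace_AAA'`` sets the window to
    all-A (trinucleotide adenosine scan); ``rule='transversion_swap'`` maps
    A<->C, G<->T within the window, ablating base-pairing potential. Variant
    IDs are ``<wildtype_id>_m<s>-<e>``; the wildtype itself is appended as a
    labelled reference record.
    """
    wt = _normalize_sequence(wildtype, wildtype_id)
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > len(wt):
        raise ValueError(f"window {window} exceeds sequence length {len(wt)}")
    if rule not in ("replace_AAA", "transversion_swap"):
        raise ValueError(f"unknown scanning rule {rule!r}")
    fam = family or f"candidate:scan_{rule}"
    out = []
    for s0 in range(0, len(wt) - window + 1, step):
        s, e = s0 + 1, s0 + window
        win = wt[s0 : s0 + window]
        repl = "A" * window if rule == "replace_AAA" else transversion_swap(win)
        out.append(
            ConstructRecord(f"{wildtype_id}_m{s}-{e}", wt[:s0] + repl + wt[s0 + window :], fam)
        )
    out.append(ConstructRecord(wildtype_id, wt, family="candidate:wildtype"))
    return out


def _mutate_interval(seq: str, interval: tuple[int, int]) -> str:
    i, j = interval
    return seq[: i - 1] + complement(seq[i - 1 : j]) + seq[j:]


def design_helix_mutants(
    wildtype: str, region: PairedRegion, wildtype_id: str = "WT"
) -> list[ConstructRecord]:
    """Left / right / compensatory mutants of a base-paired region.

    L complements every nucleotide of the left interval in place (no strand
    reversal), R the right interval, C both — so C restores the pairing
    potential that L and R individually destroy.
    """
    wt = _normalize_sequence(wildtype, wildtype_id)
    if region.right[1] > len(wt):
        raise ValueError(
            f"region {region.name} extends past sequence length {len(wt)}"
        )
    fam = f"candidate:helix_{region.name}"
    l_seq = _mutate_interval(wt, region.left)
    r_seq = _mutate_interval(wt, region.right)
    c_seq = _mutate_interval(l_seq, region.right)
    return [
        ConstructRecord(f"{wildtype_id}_{region.name}_L", l_seq, fam),
        ConstructRecord(f"{wildtype_id}_{region.name}_R", r_seq, fam),
        ConstructRecord(f"{wildtype_id}_{region.name}_C", c_seq, fam),
    ]


def design_rrna_tiles(
    rrna: str, tile_len: int, step: int, id_prefix: str = "rrna_tile"
) -> list[ConstructRecord]:
    """Tiled array of sequences complementary to an rRNA.

    Each tile is the reverse complement of a window of the rRNA, ordered 5'→3'
    along the rRNA; IDs encode the 1-based window coordinates.
    """
    r = _normalize_sequence(rrna, id_prefix)
    if tile_len > len(r):
        raise ValueError(f"tile_len {tile_len} exceeds rRNA length {len(r)}")
    if step < 1 or tile_len < 1:
        raise ValueError("tile_len and step must be >= 1")
    out = []
    for s0 in range(0, len(r) - tile_len + 1, step):
        s, e = s0 + 1, s0 + tile_len
        out.append(
            ConstructRecord(
                f"{id_prefix}_{s}-{e}",
                revcomp(r[s0 : s0 + tile_len]),
                "candidate:rrna_complement",
            )
        )
    return out


def write_design_manifest(
    records: Sequence[ConstructRecord], rule: str, wildtype_id: str, path
) -> None:
    """TSV manifest for a designed variant set: construct_id, rule, interval, wildtype_id."""
    with open(path, "w") as fh:
        fh.write("construct_id\trule\tstart\tend\twildtype_id\n")
        for rec in records:
            if rec.construct_id == wildtype_id:
                continue
            try:
                s, e = parse_window_id(rec.construct_id)
            except ValueError:
                s = e = ""
            fh.write(f"{rec.construct_id}\t{rule}\t{s}\t{e}\t{wildtype_id}\n")
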