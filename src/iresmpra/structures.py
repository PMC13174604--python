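"""Secondary-structure records: dot-bracket (with pseudoknots) and CT parsing.

Pseudoknotted structures cannot be written with a single bracket class, so the
dot-bracket alphabet here includes ``()``, ``[]``, ``{}`` and ``<>``; each class
must be individually balanced and properly nested, while classes may cross each
other (that crossing is what makes a pseudoknot).
"""

from __future__ import annotations

from dataclasses import dataclass

_OPEN = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSE = {v: k for k, v in _OPEN.items()}


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with its base-pair list.

    ``pairs`` holds 1-based ``(i, j)`` with ``i < j``; pseudoknot pairs are
    included on equal footing with nested ones.
    """

    structure_id: str
    sequence: str
    dotbracket: str
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        n = len(self.sequence)
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise ValueError(
                    f"{self.structure_id}: pair ({i},{j}) outside sequence of length {n}"
                )


def pairs_from_dotbracket(dotbracket: str) -> tuple[tuple[int, int], ...]:
    """Base pairs of a (possibly pseudoknotted) dot-bracket string, 1-based."""
    stacks: dict[str, list[int]] = {c: [] for c in _OPEN}
    pairs = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[ch].append(pos)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            pairs.append((stack.pop(), pos))
        else:
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unclosed {opener!r} at position {stack[-1]}")
    return tuple(sorted(pairs))


def parse_dotbracket(structure_id: str, sequence: str, dotbracket: str) -> SecondaryStructure:
    seq = sequence.upper().replace("U", "T")
    if len(seq) != len(dotbracket):
        raise ValueError(
            f"{structure_id}: sequence length {len(seq)} != dot-bracket length {len(dotbracket)}"
        )
    return SecondaryStructure(structure_id, seq, dotbracket, pairs_from_dotbracket(dotbracket))


def read_structure_file(path) -> dict[str, SecondaryStructure]:
    """Read the plain-text structure format: three lines per record (>id / sequence / dot-bracket)."""
    out: dict[str, SecondaryStructure] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1} of {path}")
        sid = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"truncated structure record {sid!r} in {path}")
        if sid in out:
            raise ValueError(f"duplicate structure id {sid!r} in {path}")
        out[sid] = parse_dotbracket(sid, lines[i + 1], lines[i + 2])
        i += 3
    return out


def read_ct(path, structure_id: str | None = None) -> SecondaryStructure:
    """Read a CT-format connectivity table (single structure).

    Columns: index, base, prev, next, paired-index (0 = unpaired), natural
    index. Dot-bracket is reconstructed with nested brackets where possible and
    additional bracket classes for crossing (pseudoknot) pairs.
    """
    seq_chars: list[str] = []
    partner: list[int] = []
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError(f"empty CT file {path}")
        n = int(header[0])
        sid = structure_id or (header[1] if len(header) > 1 else "ct_structure")
        for line in fh:
            fields = line.split()
            if len(fields) < 5:
                continue
            seq_chars.append(fields[1].upper().replace("U", "T"))
            partner.append(int(fields[4]))
    if len(seq_chars) != n:
        raise ValueError(f"CT file {path}: header says {n} bases, found {len(seq_chars)}")
    pairs = tuple(
        sorted((i + 1, p) for i, p in enumerate(partner) if p > i + 1)
    )
    db = _dotbracket_from_pairs(n, pairs)
    return SecondaryStructure(sid, "".join(seq_chars), db, pairs)


def _dotbracket_from_pairs(n: int, pairs: tuple[tuple[int, int], ...]) -> str:
    classes = "([{<"
    closers = ")]}>"
    assigned: list[list[tuple[int, int]]] = [[] for _ in classes]
    for pair in pairs:
        for ci in range(len(classes)):
            if all(not _crosses(pair, q) for q in assigned[ci]):
                assigned[ci].append(pair)
                break
        else:
            raise ValueError("structure requires more than four crossing pair classes")
    out = ["."] * n
    for ci, plist in enumerate(assigned):
        for i, j in plist:
            out[i - 1] = classes[ci]
            out[j - 1] = closers[ci]
    return "".join(out)


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((a, b))
    return i < k < j < l
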