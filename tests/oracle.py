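"""Independent brute-force oracles for coordinate arithmetic.

These interpreters apply an edit script base by base and record the full
per-base correspondence between source and destination.  They share no code
with the package's block-based implementation; tests compare the two.
"""

from __future__ import annotations

import random
from collections import defaultdict


def bruteforce_apply(seq: str, instructions) -> tuple[str, list[int | None], list[int | None]]:
    """Apply (kind, pos, payload) edits one base at a time.

    Returns ``(dst_seq, dst2src, src2dst)`` where ``dst2src[d]`` is the source
    position of destination base ``d`` (None for inserted bases) and
    ``src2dst[s]`` the destination position of source base ``s`` (None for
    deleted bases).  Substituted bases keep their correspondence.
    """
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins_after: dict[int, list[str]] = defaultdict(list)
    for kind, pos, payload in instructions:
        if kind == "s":
            subs[pos] = payload[1] if isinstance(payload, tuple) else payload
        elif kind == "d":
            dels.add(pos)
        elif kind == "i":
            ins_after[pos].append(payload)
        else:
            raise ValueError(kind)

    dst_chars: list[str] = []
    dst2src: list[int | None] = []

    def emit_inserts(anchor: int) -> None:
        for chunk in ins_after.get(anchor, []):
            for ch in chunk:
                dst_chars.append(ch)
                dst2src.append(None)

    emit_inserts(-1)
    for p, base in enumerate(seq):
        if p in dels:
            pass
        elif p in subs:
            dst_chars.append(subs[p])
            dst2src.append(p)
        else:
            dst_chars.append(base)
            dst2src.append(p)
        emit_inserts(p)

    src2dst: list[int | None] = [None] * len(seq)
    for d, s in enumerate(dst2src):
        if s is not None:
            src2dst[s] = d
    return "".join(dst_chars), dst2src, src2dst


def random_edit_script(rng: random.Random, seq: str, n_edits: int):
    """A random valid instruction list over one sequence.

    Guarantees at most one s/d per position and never places an s or d on a
    position already consumed by a multi-base deletion.
    """
    length = len(seq)
    used: set[int] = set()
    instructions = []
    for _ in range(n_edits):
        kind = rng.choice(["s", "d", "i", "del_run"])
        if kind == "i":
            pos = rng.randint(-1, length - 1)
            payload = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
            instructions.append(("i", pos, payload))
            continue
        if kind == "del_run":
            run = rng.randint(1, 4)
            pos = rng.randint(0, max(0, length - run))
            if any(p in used for p in range(pos, pos + run)):
                continue
            for p in range(pos, pos + run):
                used.add(p)
                instructions.append(("d", p, seq[p]))
            continue
        pos = rng.randint(0, length - 1)
        if pos in used:
            continue
        used.add(pos)
        if kind == "s":
            alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
            instructions.append(("s", pos, (seq[pos], alt)))
        else:
            instructions.append(("d", pos, seq[pos]))
    return instructions


def expand_reference_correspondence(
    cigar: str, start: int
) -> list[int | None]:
    """Per read base, the 0-based reference position it aligns to (None for
    I/S bases); the independent expansion used to check rewritten CIGARs."""
    out: list[int | None] = []
    rpos = start
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "M=X":
            out.extend(range(rpos, rpos + ln))
            rpos += ln
        elif ch in "IS":
            out.extend([None] * ln)
        elif ch in "DN":
            rpos += ln
        elif ch == "H":
            pass
        else:
            raise ValueError(ch)
    return out
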