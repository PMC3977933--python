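"""Seeded synthetic sequence families for testing and benchmarking.

A family is one random ancestor plus n descendants derived independently by
per-site substitutions (probability ``sub_rate``, replacement drawn uniformly
from the other residues) and indels (per-site probability ``indel_rate``,
insertion or deletion with equal probability, lengths geometric with mean
``indel_mean``).  Everything is driven by one numpy Generator seed, so a
family is exactly reproducible.
"""

from __future__ import annotations

import numpy as np

from .io_formats import Alphabet, SequenceRecord, SequenceSet

_DNA_RESIDUES = "ACGT"
_PROTEIN_RESIDUES = "ARNDCQEGHILKMFPSTWYV"


def random_family(n: int = 10, length: int = 2000, sub_rate: float = 0.05,
                  indel_rate: float = 0.01, indel_mean: float = 3.0,
                  alphabet: Alphabet | str = Alphabet.DNA,
                  seed: int = 0, id_prefix: str = "seq") -> SequenceSet:
    """Generate a family of n related sequences around one random ancestor."""
    if n < 2:
        raise ValueError("a family needs at least two sequences")
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if length < 1:
        raise ValueError("length must be positive")
    alphabet = Alphabet(alphabet)
    residues = (_DNA_RESIDUES if alphabet is Alphabet.DNA
                else _PROTEIN_RESIDUES)
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, len(residues), size=length)

    records = []
    width = len(str(n))
    for t in range(n):
        seq = _mutate(ancestor, rng, len(residues), sub_rate, indel_rate,
                      indel_mean)
        body = "".join(residues[c] for c in seq)
        rid = f"{id_prefix}{t + 1:0{width}d}"
        records.append(SequenceRecord(rid, rid, body, alphabet))
    return SequenceSet(records)


def _mutate(ancestor: np.ndarray, rng: np.random.Generator, n_res: int,
            sub_rate: float, indel_rate: float,
            indel_mean: float) -> np.ndarray:
    seq = ancestor.copy()
    if sub_rate > 0:
        hit = rng.random(seq.size) < sub_rate
        # Uniform over the other residues: shift by 1..n_res-1 modulo n_res.
        seq[hit] = (seq[hit] + rng.integers(1, n_res, size=int(hit.sum()))
                    ) % n_res
    if indel_rate > 0:
        events = np.flatnonzero(rng.random(seq.size) < indel_rate)
        p = min(1.0, 1.0 / max(indel_mean, 1.0))
        pieces: list[np.ndarray] = []
        cursor = 0
        for pos in events:
            if pos < cursor:
                continue  # swallowed by a previous deletion
            size = int(rng.geometric(p))
            if rng.random() < 0.5:
                ins = rng.integers(0, n_res, size=size)
                pieces.append(seq[cursor:pos])
                pieces.append(ins)
                cursor = pos
            else:
                pieces.append(seq[cursor:pos])
                cursor = min(pos + size, seq.size)
        pieces.append(seq[cursor:])
        seq = np.concatenate(pieces) if pieces else seq
    if seq.size == 0:
        seq = rng.integers(0, n_res, size=1)
    return seq
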