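"""Shared alignment utilities.

Thin wrappers around edlib (fast edit-distance alignment), Biopython's
PairwiseAligner (protein Smith-Waterman for RT anchoring) and the mafft
binary (multiple alignment). All coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_dna(seq: str) -> np.ndarray:
    """DNA string -> uint8 array (A=0,C=1,G=2,T=3, other=255)."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode()


@dataclass
class InfixHit:
    """Best alignment of a full query inside a longer target."""

    start: int  # target coordinates, 0-based half-open
    end: int
    distance: int
    identity: float  # 1 - distance / len(query)


def best_infix(query: str, target: str, max_dist: int | None = None) -> InfixHit | None:
    """Locate `query` as an infix of `target` (edlib HW mode)."""
    if not query or not target:
        return None
    k = -1 if max_dist is None else max_dist
    res = edlib.align(query.upper(), target.upper(), mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    return InfixHit(
        start=s,
        end=e + 1,
        distance=res["editDistance"],
        identity=1.0 - res["editDistance"] / max(len(query), 1),
    )


def edit_identity(a: str, b: str) -> float:
    """Global (NW) identity between two sequences, 1 - dist/max(len)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def shared_kmer_box(a: str, b: str, k: int = 11) -> tuple[int, int] | None:
    """Bounding interval on `a` of k-mers shared with `b` (None if no sharing)."""
    kb = set()
    bu = b.upper()
    for i in range(len(bu) - k + 1):
        kb.add(bu[i : i + k])
    lo, hi = None, None
    au = a.upper()
    for i in range(len(au) - k + 1):
        if au[i : i + k] in kb:
            if lo is None:
                lo = i
            hi = i + k
    if lo is None:
        return None
    return lo, hi


def local_identity(a: str, b: str, k: int = 11) -> tuple[float, float]:
    """(identity, coverage) of the best shared block of `a` (the shorter) in `b`.

    The homologous block on `a` is delimited by shared k-mers; identity is the
    edit identity of that block aligned as an infix of `b`; coverage is the
    block's fraction of `a`. Non-homologous pairs share (almost) no k-mers and
    score ~0 on both.
    """
    if len(a) > len(b):
        a, b = b, a
    box = shared_kmer_box(a, b, k=k)
    if box is None:
        return 0.0, 0.0
    lo, hi = box
    block = a[lo:hi]
    hit = best_infix(block, b)
    if hit is None:
        return 0.0, 0.0
    coverage = len(block) / max(len(a), 1)
    return hit.identity, coverage


def pairwise_align(query: str, target: str, mode: str = "NW") -> tuple[str, str]:
    """Gapped pairwise alignment (edlib); returns (aligned_query, aligned_target)."""
    res = edlib.align(query.upper(), target.upper(), mode=mode, task="path")
    nice = edlib.getNiceAlignment(res, query.upper(), target.upper())
    return nice["query_aligned"], nice["target_aligned"]


def project_to_reference(seq: str, reference: str) -> np.ndarray:
    """Align `seq` to `reference` and return its bases in reference
    coordinates (uint8 codes; 255 where the reference base is deleted in
    `seq`; insertions relative to the reference are dropped)."""
    qa, ta = pairwise_align(reference, seq)
    out = np.full(len(reference), 255, dtype=np.uint8)
    ref_pos = 0
    for qc, tc in zip(qa, ta):
        if qc != "-":
            if tc != "-":
                out[ref_pos] = _BASE_CODE[ord(tc)]
            ref_pos += 1
    return out


# ---------------------------------------------------------------------------
# multiple alignment (mafft)
# ---------------------------------------------------------------------------


def align_sequences(seqs: dict[str, str] | list[tuple[str, str]]) -> dict[str, str]:
    """Multiple-align sequences with mafft; returns name -> aligned sequence.

    Input order is preserved in the output dict. Sequences that are already
    equal length and gap-free are returned untouched (the common case for
    simulator output, which contains no indels).
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        return {}
    lens = {len(s) for _, s in items}
    if len(lens) == 1:
        return dict(items)
    mafft = shutil.which("mafft")
    if mafft is None:  # pragma: no cover - mafft is part of the toolchain
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = os.path.join(tmp, "in.fa")
        with open(fin, "w") as fh:
            for i, (_, s) in enumerate(items):
                fh.write(f">s{i}\n{s}\n")
        proc = subprocess.run(
            [mafft, "--quiet", "--retree", "2", fin],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned: list[str] = []
    cur: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if cur:
                aligned.append("".join(cur))
            cur = []
        else:
            cur.append(line.strip())
    if cur:
        aligned.append("".join(cur))
    if len(aligned) != len(items):  # pragma: no cover - defensive
        raise RuntimeError("mafft returned an unexpected number of records")
    return {name: aln.upper() for (name, _), aln in zip(items, aligned)}
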