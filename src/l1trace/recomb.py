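"""Recombination detection between family consensus sequences.

Two complementary detectors:

* ``maxchi_scan`` — the substitution-distribution test: within each sequence
  triplet, the variable sites of each pair are partitioned by a sliding
  boundary and the 2x2 chi-square of (match/mismatch) x (left/right) is
  maximized over boundaries; significance comes from permuting the order of
  variable sites, with a Bonferroni correction across the pairs tested.
* ``bootscan`` — the phylogenetic test: sliding windows are bootstrapped and
  the fraction of replicates in which each reference is the target's nearest
  neighbor traces a support curve whose crossover marks the breakpoint.

Candidate breakpoints are verified by comparing bootstrap-annotated NJ trees
built from the alignment columns on either side: a breakpoint is confirmed
when the putative recombinant changes well-supported sister groups between
the two trees. Only large-segment events are considered (a minimum number
of columns on each side of the boundary).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._align import encode_dna
from ._trees import (
    Node,
    annotate_support,
    leaf_sister_set,
    neighbor_joining,
    newick,
    patristic_to_leaf,
    split_support,
)
from .chronology import tn93_matrix

#: minimum alignment columns required on each side of a reported boundary
#: ("large segment" stringency); shrinks to L//4 on short alignments.
MIN_SEGMENT = 300


@dataclass
class BreakpointReport:
    seq_pair: tuple[str, str]
    position: int  # 1-based alignment column: last column of the 5' segment
    plateau: tuple[int, int]  # 1-based [first, last] column with the same statistic
    statistic: float
    p_value: float
    window: int
    verified: bool = False
    position_orf2: int | None = None
    verification: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _as_matrix(alignment) -> tuple[list[str], np.ndarray]:
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    names = [nm for nm, _ in items]
    lens = {len(s) for _, s in items}
    if len(lens) != 1:
        raise ValueError("sequences must be aligned to equal length")
    mat = np.stack([encode_dna(s) for _, s in items])
    return names, mat


def _chi2_curve(v: np.ndarray) -> np.ndarray:
    """2x2 chi-square for every cut t=1..V-1 of a boolean mismatch vector.

    v may be 1-D (V,) or 2-D (B, V); returns (V-1,) or (B, V-1)."""
    v = np.atleast_2d(v).astype(float)
    B, V = v.shape
    t = np.arange(1, V, dtype=float)
    m_l = np.cumsum(v, axis=1)[:, :-1]
    M = v.sum(axis=1, keepdims=True)
    a = m_l
    b = t[None, :] - m_l
    c = M - m_l
    d = (V - t)[None, :] - c
    num = V * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(den > 0, num / den, 0.0)
    return chi[0] if chi.shape[0] == 1 else chi


def maxchi_scan(
    alignment,
    window: int = 50,
    permutations: int = 1000,
    alpha: float = 0.05,
    min_segment: int = MIN_SEGMENT,
    orf2_offset: int = 0,
    seed: int = 0,
) -> list[BreakpointReport]:
    """MaxChi breakpoint scan over all sequence triplets.

    For each pair within a triplet, sites at which the triplet is variable
    are split by a sliding boundary and the match/mismatch chi-square is
    maximized; the null distribution comes from `permutations` shuffles of
    the variable-site order. A pair is reported when its best permutation
    p-value passes the Bonferroni threshold alpha / (number of
    triplet-pair tests run), which controls the familywise error; note the
    permutation count must exceed that number of tests divided by alpha
    for a detection to be possible at all. `window` is the minimum
    number of variable sites required on each side of a boundary; boundaries
    are additionally kept `min_segment` columns (or L/4 if smaller) away
    from the alignment edges. The reported position is the 1-based column of
    the last variable site assigned to the 5' segment, with the equally
    optimal plateau alongside; `orf2_offset` also projects the position into
    ORF2-local coordinates.
    """
    names, mat = _as_matrix(alignment)
    n, L = mat.shape
    if n < 3:
        raise ValueError("MaxChi needs at least three sequences")
    if L < 4 * window:
        raise ValueError(f"alignment length {L} < 4 x window ({window})")
    min_seg = min(min_segment, L // 4)
    rng = np.random.default_rng(seed)
    best: dict[tuple[str, str], BreakpointReport] = {}
    n_tests = 0  # every (triplet, pair) scan counts toward Bonferroni
    for ti, tj, tk in itertools.combinations(range(n), 3):
        trip = mat[[ti, tj, tk]]
        good = (trip < 4).all(axis=0)
        poly = good & ~((trip[0] == trip[1]) & (trip[1] == trip[2]))
        cols = np.nonzero(poly)[0]
        if cols.size < 2 * window:
            continue
        for a, b in itertools.combinations((ti, tj, tk), 2):
            pair = (names[a], names[b])
            n_tests += 1
            v = (mat[a, cols] != mat[b, cols]).astype(np.uint8)
            V = v.size
            chi = _chi2_curve(v)
            t = np.arange(1, V)
            ok = (
                (t >= window)
                & (V - t >= window)
                & (cols[t - 1] + 1 >= min_seg)
                & (L - cols[t] >= min_seg)
            )
            if not ok.any():
                continue
            chi_ok = np.where(ok, chi, -np.inf)
            t_star = int(np.argmax(chi_ok)) + 1
            stat = float(chi_ok[t_star - 1])
            if stat <= 0:
                continue
            perms = rng.permuted(np.tile(v, (permutations, 1)), axis=1)
            null = np.where(ok[None, :], _chi2_curve(perms), -np.inf).max(axis=1)
            p = float((1 + (null >= stat).sum()) / (permutations + 1))
            pos = int(cols[t_star - 1]) + 1  # 1-based
            plateau = (pos, int(cols[t_star]))  # same statistic anywhere in between
            rep = BreakpointReport(
                seq_pair=pair,
                position=pos,
                plateau=plateau,
                statistic=stat,
                p_value=p,
                window=window,
                position_orf2=pos - orf2_offset if orf2_offset else pos,
            )
            prev = best.get(pair)
            if prev is None or stat > prev.statistic:
                best[pair] = rep
    alpha_eff = alpha / max(n_tests, 1)
    out = [r for r in best.values() if r.p_value <= alpha_eff]
    out.sort(key=lambda r: (r.p_value, -r.statistic, r.seq_pair))
    return out


def bootscan(
    target: str,
    references: dict[str, str],
    window: int = 200,
    step: int = 20,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window bootstrap support for each reference being the
    target's nearest neighbor.

    `target` is the aligned target sequence; `references` maps name ->
    aligned sequence (all equal length). Returns one row per window
    (start column, 1-based) and one support column per reference.
    """
    names = ["__target__"] + list(references)
    mat = np.stack([encode_dna(target)] + [encode_dna(s) for s in references.values()])
    L = mat.shape[1]
    if window >= L:
        raise ValueError(f"window {window} >= alignment length {L}")
    if len(references) < 2:
        raise ValueError("need at least two references")
    rng = np.random.default_rng(seed)
    rows = []
    for start in range(0, L - window + 1, step):
        sub = mat[:, start : start + window]
        wins = {nm: 0 for nm in references}
        for _ in range(reps):
            cols = rng.integers(0, window, size=window)
            boot = sub[:, cols]
            V = (boot < 4).astype(np.float64)
            nv = V @ V.T
            matches = sum(
                (boot == b).astype(np.float64) @ (boot == b).astype(np.float64).T
                for b in range(4)
            )
            D = 1.0 - matches / np.where(nv > 0, nv, 1.0)
            np.fill_diagonal(D, 0.0)
            tree = neighbor_joining(D, names)
            dist = patristic_to_leaf(tree, "__target__")
            nearest = min(sorted(dist), key=lambda nm: dist[nm])
            wins[nearest] += 1
        rows.append(
            {"window_start": start + 1, **{nm: wins[nm] / reps for nm in references}}
        )
    return pd.DataFrame(rows)


def _nj_boot(
    mat: np.ndarray, names: list[str], reps: int, rng: np.random.Generator
) -> tuple[Node, list[Node]]:
    def distmat(m: np.ndarray) -> np.ndarray:
        return np.nan_to_num(tn93_matrix(m), nan=0.75)

    tree = neighbor_joining(distmat(mat), names)
    boots = []
    L = mat.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        boots.append(neighbor_joining(distmat(mat[:, cols]), names))
    return tree, boots


def verify_breakpoint(
    report: BreakpointReport,
    alignment,
    out_groups: list[str] | None = None,
    support_threshold: float = 70.0,
    min_side: int = 200,
    bootstrap_reps: int = 200,
    seed: int = 0,
) -> BreakpointReport:
    """Confirm a breakpoint by side-tree comparison.

    Bootstrap-annotated NJ trees are built on columns [1, position] and
    (position, L]; the report is verified when one of the paired sequences
    has a different, well-supported (>= support_threshold on both sides)
    sister group in the two trees. Sides shorter than `min_side` columns
    skip verification (flagged in the report).
    """
    names, mat = _as_matrix(alignment)
    L = mat.shape[1]
    pos = report.position
    if pos < min_side or L - pos < min_side:
        return replace(
            report,
            verified=False,
            verification={"skipped": f"side shorter than {min_side} columns"},
        )
    rng = np.random.default_rng(seed)
    root_with = out_groups[0] if out_groups else next(
        nm for nm in sorted(names) if nm not in report.seq_pair
    )
    sides = {}
    trees = {}
    for side_name, sub in (("5p", mat[:, :pos]), ("3p", mat[:, pos:])):
        tree, boots = _nj_boot(sub, names, bootstrap_reps, rng)
        annotate_support(tree, boots)
        trees[side_name] = newick(tree)
        all_leaves = frozenset(names)
        per_target = {}
        for target in report.seq_pair:
            sis = leaf_sister_set(tree, target, root_with=root_with)
            sup = split_support(frozenset([target]) | sis, all_leaves, boots)
            per_target[target] = (sis, sup)
        sides[side_name] = per_target
    verification = {"trees": trees}
    verified = False
    for target in report.seq_pair:
        sis5, sup5 = sides["5p"][target]
        sis3, sup3 = sides["3p"][target]
        verification[target] = {
            "sister_5p": sorted(sis5),
            "support_5p": sup5,
            "sister_3p": sorted(sis3),
            "support_3p": sup3,
        }
        if (
            sis5 != sis3
            and sup5 >= support_threshold
            and sup3 >= support_threshold
        ):
            verified = True
    return replace(report, verified=verified, verification=verification)


def reports_to_frame(reports: list[BreakpointReport]) -> pd.DataFrame:
    cols = [
        "seq_a", "seq_b", "position", "plateau_start", "plateau_end",
        "position_orf2", "statistic", "p_value", "window", "verified",
    ]
    rows = [
        {
            "seq_a": r.seq_pair[0],
            "seq_b": r.seq_pair[1],
            "position": r.position,
            "plateau_start": r.plateau[0],
            "plateau_end": r.plateau[1],
            "position_orf2": r.position_orf2,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "window": r.window,
            "verified": r.verified,
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=cols)
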