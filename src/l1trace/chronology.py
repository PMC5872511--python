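"""Dating L1 families under a fossil-calibrated molecular clock.

Family ages come from the average pairwise divergence of the 3'-end region
(end of ORF2 + 3'UTR), with CpG dinucleotides and 3'UTR polypurine tracts
masked on the consensus before distances are taken. Divergence `d` between
two copies accumulates along both lineages since insertion, so

    age (Myr) = d / (2 r)

with the per-lineage rate r calibrated to 0.13 %/Myr by the 56-Myr
Hippomorpha/Ceratomorpha split. Divergence *from consensus* accumulates
along a single lineage, so extinction times use d / r.

Divergences are fractions internally; the clock rate is in %/Myr to match
the printed convention, and conversions multiply by 100 in one place.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._align import encode_dna, project_to_reference


class InsufficientSignalError(ValueError):
    """Too few unmasked columns to estimate a divergence."""


@dataclass
class DivergenceEstimate:
    mean: float  # fraction
    se: float
    n_pairs: int
    region: str = ""

    def __post_init__(self) -> None:
        if self.mean < 0 or self.se < 0:
            raise ValueError("divergence mean and SE must be >= 0")


@dataclass
class CalibratedClock:
    rate: float  # %/Myr per lineage
    t_cal: float = 56.0  # Myr, Hippomorpha/Ceratomorpha split
    calibration_divergence: float | None = None  # fraction, if anchored

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.t_cal <= 0:
            raise ValueError("rate and t_cal must be positive")

    @classmethod
    def from_calibration(cls, calibration_divergence: float, t_cal: float = 56.0):
        """Anchor the clock: a pairwise divergence (fraction) attained at the
        calibration split gives rate = 100 * d / (2 * t_cal) %/Myr."""
        rate = 100.0 * calibration_divergence / (2.0 * t_cal)
        return cls(rate=rate, t_cal=t_cal, calibration_divergence=calibration_divergence)


DEFAULT_CLOCK = CalibratedClock(rate=0.13)


@dataclass
class AgeEstimate:
    age: float  # Myr
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.age <= self.ci_high:
            raise ValueError("need ci_low <= age <= ci_high")


@dataclass
class RateComparison:
    mean_a: float
    mean_b: float
    slowdown: float  # 1 - mean_b / mean_a
    p_value: float  # Welch (unpaired) or paired t
    p_rank: float  # Mann-Whitney / Wilcoxon
    n_loci: int
    paired: bool


# ---------------------------------------------------------------------------
# corrected distances
# ---------------------------------------------------------------------------


def _jc_from_p(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan
    return -0.75 * math.log(arg)


def tn93_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Tamura-Nei (1993) distance from paired base codes (A=0,C=1,G=2,T=3;
    other codes ignored). Falls back to Jukes-Cantor when a base class is
    absent, NaN on saturation."""
    valid = (a < 4) & (b < 4)
    a, b = a[valid], b[valid]
    n = a.size
    if n == 0:
        raise InsufficientSignalError("no comparable sites")
    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    gA, gC, gG, gT = counts / (2.0 * n)
    gR, gY = gA + gG, gC + gT
    diff = a != b
    p1 = float((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).mean())
    p2 = float((((a == 1) & (b == 3)) | ((a == 3) & (b == 1))).mean())
    q = float(diff.mean()) - p1 - p2
    if min(gA * gG, gC * gT, gR * gY) <= 0:
        return _jc_from_p(float(diff.mean()))
    w1 = 1.0 - p1 * gR / (2.0 * gA * gG) - q / (2.0 * gR)
    w2 = 1.0 - p2 * gY / (2.0 * gC * gT) - q / (2.0 * gY)
    w3 = 1.0 - q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0:
        return math.nan
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    return -(k1 * math.log(w1) + k2 * math.log(w2) + k3 * math.log(w3))


def tn93_matrix(codes: np.ndarray) -> np.ndarray:
    """All-pairs TN93 distance matrix from an (n, L) uint8 code matrix.

    Vectorised with one-hot matrix products so thousand-replicate
    bootstraps stay cheap; entries fall back to Jukes-Cantor where a base
    class is absent and to NaN on saturation (mirroring tn93_from_codes).
    """
    n, L = codes.shape
    X = [(codes == b).astype(np.float64) for b in range(4)]
    V = (codes < 4).astype(np.float64)
    nv = V @ V.T
    nv_safe = np.where(nv > 0, nv, np.nan)
    matches = sum(x @ x.T for x in X)
    p1 = (X[0] @ X[2].T + X[2] @ X[0].T) / nv_safe  # A<->G
    p2 = (X[1] @ X[3].T + X[3] @ X[1].T) / nv_safe  # C<->T
    pdist = 1.0 - matches / nv_safe
    q = pdist - p1 - p2
    g = [(x @ V.T + (x @ V.T).T) / (2 * nv_safe) for x in X]
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = 1.0 - p1 * gR / (2 * gA * gG) - q / (2 * gR)
        w2 = 1.0 - p2 * gY / (2 * gC * gT) - q / (2 * gY)
        w3 = 1.0 - q / (2 * gR * gY)
        k1 = 2 * gA * gG / gR
        k2 = 2 * gC * gT / gY
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        tn = -(k1 * np.log(w1) + k2 * np.log(w2) + k3 * np.log(w3))
        jc = -0.75 * np.log(1.0 - 4.0 * pdist / 3.0)
        degenerate = (gA * gG <= 0) | (gC * gT <= 0) | (gR * gY <= 0)
        out = np.where(degenerate, jc, tn)
    np.fill_diagonal(out, 0.0)
    return out


def tn93_distance(seq_a: str, seq_b: str, keep: np.ndarray | None = None) -> float:
    """TN93 distance between two equal-length aligned sequences; `keep` is an
    optional boolean column mask."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = encode_dna(seq_a), encode_dna(seq_b)
    if keep is not None:
        a, b = a[keep], b[keep]
    return tn93_from_codes(a, b)


def p_distance(seq_a: str, seq_b: str) -> float:
    a, b = encode_dna(seq_a), encode_dna(seq_b)
    valid = (a < 4) & (b < 4)
    return float((a[valid] != b[valid]).mean())


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------


def mask_keep(
    consensus: str,
    utr3_span: tuple[int, int] | None = None,
    min_purine_run: int = 5,
) -> np.ndarray:
    """Boolean keep-mask over consensus columns: CpG dinucleotides (both
    positions) are masked everywhere; runs of >= `min_purine_run` consecutive
    A/G are masked within the 3'UTR span. Idempotent by construction (the
    mask depends only on the consensus)."""
    codes = encode_dna(consensus)
    keep = np.ones(len(consensus), dtype=bool)
    cpg = (codes[:-1] == 1) & (codes[1:] == 2)
    keep[:-1] &= ~cpg
    keep[1:] &= ~cpg
    if utr3_span is not None:
        s, e = utr3_span
        purine = (codes == 0) | (codes == 2)
        run = 0
        for i in range(s, min(e, len(consensus))):
            if purine[i]:
                run += 1
                if run == min_purine_run:
                    keep[i - min_purine_run + 1 : i + 1] = False
                elif run > min_purine_run:
                    keep[i] = False
            else:
                run = 0
    return keep


def _project(seq: str, consensus: str) -> np.ndarray:
    if len(seq) == len(consensus):
        return encode_dna(seq)
    return project_to_reference(seq, consensus)


def masked_divergence(
    seqs: list[str],
    consensus: str,
    window: tuple[int, int] | None = None,
    utr3_span: tuple[int, int] | None = None,
    min_sites: int = 50,
    min_purine_run: int = 5,
) -> DivergenceEstimate:
    """Mean pairwise TN93 distance among `seqs` over unmasked consensus
    columns (optionally restricted to a 3'-end `window`), with the SE of the
    mean taken over pair distances.

    Sequences of consensus length are compared column-wise; others are first
    projected into consensus coordinates by pairwise alignment.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    keep = mask_keep(consensus, utr3_span=utr3_span, min_purine_run=min_purine_run)
    if window is not None:
        w = np.zeros(len(consensus), dtype=bool)
        w[window[0] : window[1]] = True
        keep &= w
    if int(keep.sum()) < min_sites:
        raise InsufficientSignalError(
            f"only {int(keep.sum())} unmasked columns (< {min_sites})"
        )
    proj = [_project(s, consensus)[keep] for s in seqs]
    dists = []
    for a, b in itertools.combinations(proj, 2):
        d = tn93_from_codes(a, b)
        if not math.isnan(d):
            dists.append(d)
    if not dists:
        raise InsufficientSignalError("no valid pairwise comparisons")
    arr = np.asarray(dists)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    region = f"cols[{window[0]}:{window[1]}]" if window else "full"
    return DivergenceEstimate(
        mean=float(arr.mean()), se=se, n_pairs=arr.size, region=region
    )


def divergence_from_consensus(
    seqs: list[str],
    consensus: str,
    window: tuple[int, int] | None = None,
    utr3_span: tuple[int, int] | None = None,
    min_sites: int = 50,
    min_purine_run: int = 5,
) -> np.ndarray:
    """Per-sequence masked TN93 distance to the consensus (single-lineage
    divergence)."""
    keep = mask_keep(consensus, utr3_span=utr3_span, min_purine_run=min_purine_run)
    if window is not None:
        w = np.zeros(len(consensus), dtype=bool)
        w[window[0] : window[1]] = True
        keep &= w
    if int(keep.sum()) < min_sites:
        raise InsufficientSignalError(
            f"only {int(keep.sum())} unmasked columns (< {min_sites})"
        )
    cons = encode_dna(consensus)[keep]
    return np.array([tn93_from_codes(_project(s, consensus)[keep], cons) for s in seqs])


# ---------------------------------------------------------------------------
# clock conversion
# ---------------------------------------------------------------------------


def divergence_to_age(
    d: DivergenceEstimate | float, clock: CalibratedClock = DEFAULT_CLOCK
) -> AgeEstimate:
    """Convert a pairwise divergence (fraction) to Myr via age = d / (2 r)."""
    if isinstance(d, DivergenceEstimate):
        mean, se = d.mean, d.se
    else:
        mean, se = float(d), 0.0
    if mean < 0:
        raise ValueError("divergence must be >= 0")
    denom = 2.0 * clock.rate  # %/Myr over both lineages
    age = 100.0 * mean / denom
    return AgeEstimate(
        age=age,
        ci_low=100.0 * max(mean - se, 0.0) / denom,
        ci_high=100.0 * (mean + se) / denom,
    )


def single_lineage_age(d: float, clock: CalibratedClock = DEFAULT_CLOCK) -> float:
    """Myr for a divergence accumulated along one lineage (e.g. insert vs
    consensus): age = d / r."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    return 100.0 * d / clock.rate


# ---------------------------------------------------------------------------
# extinction profiling
# ---------------------------------------------------------------------------


@dataclass
class ExtinctionProfile:
    counts: np.ndarray
    bin_edges: np.ndarray  # divergence fractions
    peak_divergence: float  # modal bin centre
    cessation_divergence: float  # minimum observed divergence
    onset_divergence: float  # maximum observed divergence
    cessation_myr: float
    onset_myr: float
    n_members: int


def extinction_profile(
    divergences: np.ndarray,
    clock: CalibratedClock = DEFAULT_CLOCK,
    bin_width: float = 0.005,
    min_members: int = 20,
) -> ExtinctionProfile:
    """Histogram of per-insert divergence-from-consensus for one family.

    The minimum divergence marks amplification cessation (extinction) and the
    maximum its onset; both convert to Myr along a single lineage (d / r).
    """
    d = np.asarray(divergences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < min_members:
        raise ValueError(f"need >= {min_members} members, got {d.size}")
    top = max(float(d.max()), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    peak = float(edges[int(np.argmax(counts))] + bin_width / 2)
    dmin, dmax = float(d.min()), float(d.max())
    return ExtinctionProfile(
        counts=counts,
        bin_edges=edges,
        peak_divergence=peak,
        cessation_divergence=dmin,
        onset_divergence=dmax,
        cessation_myr=single_lineage_age(dmin, clock),
        onset_myr=single_lineage_age(dmax, clock),
        n_members=int(d.size),
    )


# ---------------------------------------------------------------------------
# between-lineage rate comparison
# ---------------------------------------------------------------------------


def compare_rates(
    loci_a: np.ndarray, loci_b: np.ndarray, paired: bool = False
) -> RateComparison:
    """Compare divergence-from-consensus panels from two genomes.

    slowdown = 1 - mean_b / mean_a; significance by Welch's t (unpaired) or
    the paired t-test, with a rank-based test reported alongside.
    """
    a = np.asarray(loci_a, dtype=float)
    b = np.asarray(loci_b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired comparison needs equal-length panels")
    if min(a.size, b.size) < 10:
        raise ValueError("need at least 10 loci per panel")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a == 0:
        raise ValueError("slowdown undefined: mean_a is 0")
    slowdown = 1.0 - mean_b / mean_a
    if paired and np.array_equal(a, b):
        p_t, p_r = 1.0, 1.0
    elif a.std() == 0 and b.std() == 0:
        p_t = p_r = 1.0 if mean_a == mean_b else 0.0
    elif paired:
        p_t = float(stats.ttest_rel(a, b).pvalue)
        p_r = float(stats.wilcoxon(a, b, zero_method="zsplit").pvalue)
    else:
        p_t = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        p_r = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return RateComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        slowdown=slowdown,
        p_value=p_t,
        p_rank=p_r,
        n_loci=int(min(a.size, b.size)),
        paired=paired,
    )


def overall_slowdown(
    panels: list[tuple[np.ndarray, np.ndarray]], paired: bool = False
) -> tuple[float, list[RateComparison]]:
    """Mean of per-family slowdowns over several (panel_a, panel_b) pairs."""
    comparisons = [compare_rates(a, b, paired=paired) for a, b in panels]
    return float(np.mean([c.slowdown for c in comparisons])), comparisons


def panel_slowdown_from_means(means: list[tuple[float, float]]) -> float:
    """Overall slowdown from per-family mean divergences (e.g. printed
    summary values): mean over families of 1 - mean_b / mean_a."""
    return float(np.mean([1.0 - b / a for a, b in means]))


# ---------------------------------------------------------------------------
# per-family chronology table
# ---------------------------------------------------------------------------


def family_chronology(
    families: list,
    elements_by_id: dict[str, object],
    clock: CalibratedClock = DEFAULT_CLOCK,
    region_len: int = 600,
    copy_records: dict[str, object] | None = None,
):
    """Per-family summary table: consensus length, masked 3'-end pairwise
    divergence (mean +/- SE), divergence from consensus (mean +/- SE), age
    with CI, and copy numbers when provided.

    Member 3' windows are taken with a small margin so that boundary jitter
    from motif annotation is absorbed by alignment-based projection onto the
    consensus window rather than shifting columns.
    """
    import pandas as pd

    rows = []
    for fam in families:
        cons = fam.consensus
        cw = cons[-region_len:]
        utr3 = fam.consensus_spans.get("3UTR")
        utr3_local = None
        if utr3:
            off = len(cons) - region_len
            utr3_local = (max(utr3[0] - off, 0), max(utr3[1] - off, 0))
        windows = []
        for eid in fam.members:
            e = elements_by_id[eid]
            end = e.feature_spans["3UTR"][1]
            windows.append(e.sequence[max(end - region_len - 20, 0) : end])
        pairwise = masked_divergence(windows, cw, utr3_span=utr3_local)
        age = divergence_to_age(pairwise, clock)
        from_cons = divergence_from_consensus(windows, cw, utr3_span=utr3_local)
        from_cons = from_cons[~np.isnan(from_cons)]
        fc_mean = float(from_cons.mean()) if from_cons.size else math.nan
        fc_se = (
            float(from_cons.std(ddof=1) / math.sqrt(from_cons.size))
            if from_cons.size > 1
            else 0.0
        )
        row = {
            "family": fam.name,
            "n_members": fam.n_members,
            "consensus_length": len(cons),
            "pairwise_divergence_pct": round(100 * pairwise.mean, 2),
            "pairwise_divergence_se_pct": round(100 * pairwise.se, 2),
            "divergence_from_consensus_pct": round(100 * fc_mean, 2),
            "divergence_from_consensus_se_pct": round(100 * fc_se, 2),
            "age_myr": round(age.age, 1),
            "age_ci_low_myr": round(age.ci_low, 1),
            "age_ci_high_myr": round(age.ci_high, 1),
        }
        if copy_records and fam.name in copy_records:
            rec = copy_records[fam.name]
            row.update(
                n_total=rec.n_total,
                n_fl_utr=rec.n_fl_utr,
                n_fl_complete=rec.n_fl_complete,
            )
        rows.append(row)
    return pd.DataFrame(rows)
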