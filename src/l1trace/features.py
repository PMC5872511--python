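"""Per-family genome annotation and sequence-feature analyses.

Covers the bookkeeping around the dated family catalogue: total and
full-length copy numbers per family (full length estimated two ways — by
5'UTR-bearing genomic fragments, and by complete harvested elements),
tandem-repeat content of promoters, the presence/absence matrix of the
short motifs of ORF1's length polymorphic region (LPR), and a global
counting-based dN/dS (Nei-Gojobori 1986 with Jukes-Cantor correction).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._align import encode_dna, revcomp

log = logging.getLogger(__name__)

#: genomic fragments of the same family/strand closer than this are merged
MERGE_DISTANCE = 50
SEED_K = 12
MIN_SEEDS = 5
MAX_SEED_GAP = 500
#: fragments must span at least this many bp and carry at least this many
#: seeds per bp; kills single-shared-word decoy chains on random sequence
MIN_SPAN = 100
MIN_SEED_DENSITY = 0.02


@dataclass
class ConsensusEntry:
    sequence: str
    feature_spans: dict[str, tuple[int, int]] = field(default_factory=dict)


def library_from_families(families) -> dict[str, ConsensusEntry]:
    return {
        f.name: ConsensusEntry(sequence=f.consensus, feature_spans=f.consensus_spans)
        for f in families
    }


@dataclass
class CopyNumberRecord:
    family: str
    n_total: int = 0
    n_fl_utr: int = 0
    n_fl_complete: int = 0
    fragments: list[dict] = field(default_factory=list)

    def check(self) -> None:
        assert self.n_fl_complete <= self.n_fl_utr <= self.n_total, (
            f"{self.family}: copy-number ordering violated "
            f"({self.n_fl_complete} <= {self.n_fl_utr} <= {self.n_total})"
        )


@dataclass
class OmegaEstimate:
    dn: float
    ds: float
    omega: float | None  # None when ds == 0

    def __post_init__(self) -> None:
        if self.dn < 0 or self.ds < 0:
            raise ValueError("dn and ds must be >= 0")


@dataclass
class RepeatArray:
    unit_length: int
    copies: float
    start: int
    end: int
    unit: str


# ---------------------------------------------------------------------------
# fragment scan (copy numbers)
# ---------------------------------------------------------------------------


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, packed k-mer codes) for all valid k-mers of a sequence."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    for j in range(k):
        vals = vals * 4 + codes[j : j + n]
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    ok = (cbad[k:] - cbad[:-k]) == 0
    pos = np.nonzero(ok)[0]
    return pos, vals[pos]


def _chain_hits(
    gpos: np.ndarray, cpos: np.ndarray, k: int, max_gap: int
) -> list[tuple[int, int, int, int, int]]:
    """Chain co-linear seed hits into fragments.

    Returns (g_start, g_end, c_start, c_end, n_seeds) tuples."""
    if gpos.size == 0:
        return []
    diag = gpos - cpos
    order = np.lexsort((gpos, diag))
    gpos, cpos, diag = gpos[order], cpos[order], diag[order]
    out = []
    s = 0
    for i in range(1, gpos.size + 1):
        if (
            i == gpos.size
            or diag[i] - diag[i - 1] > 100
            or gpos[i] - gpos[i - 1] > max_gap
        ):
            g = gpos[s:i]
            c = cpos[s:i]
            out.append(
                (int(g.min()), int(g.max()) + k, int(c.min()), int(c.max()) + k, i - s)
            )
            s = i
    return out


def assign_fragments(
    genome: dict[str, str],
    library: dict[str, ConsensusEntry],
    k: int = SEED_K,
    min_seeds: int = MIN_SEEDS,
    max_gap: int = MAX_SEED_GAP,
    merge_distance: int = MERGE_DISTANCE,
    min_span: int = MIN_SPAN,
    min_density: float = MIN_SEED_DENSITY,
) -> pd.DataFrame:
    """Seed-and-chain assignment of genomic fragments to family consensuses.

    Each fragment is assigned to the single best-matching family (seed
    count; ties go to the alphabetically first family, logged); fragments of
    the same family and strand within `merge_distance` bp are merged.
    Columns: contig, start, end, strand, family, cons_start, cons_end,
    n_seeds.
    """
    frags = []
    for contig in sorted(genome):
        codes = encode_dna(genome[contig])
        gpos, gval = _kmer_codes(codes, k)
        if gpos.size == 0:
            continue
        order = np.argsort(gval, kind="stable")
        gval_sorted = gval[order]
        gpos_sorted = gpos[order]
        for family in sorted(library):
            cons = library[family].sequence
            for strand, cseq in (("+", cons), ("-", revcomp(cons))):
                cpos, cval = _kmer_codes(encode_dna(cseq), k)
                lo = np.searchsorted(gval_sorted, cval, side="left")
                hi = np.searchsorted(gval_sorted, cval, side="right")
                g_list, c_list = [], []
                for King, (l, h) in zip(cpos, zip(lo, hi)):
                    if h > l:
                        g_list.append(gpos_sorted[l:h])
                        c_list.append(np.full(h - l, King))
                if not g_list:
                    continue
                gh = np.concatenate(g_list)
                ch = np.concatenate(c_list)
                # chain in the search orientation (diagonals are constant
                # there); '-' spans convert to consensus-forward afterwards
                for g0, g1, c0, c1, ns in _chain_hits(gh, ch, k, max_gap):
                    span = g1 - g0
                    if ns < min_seeds or span < min_span or ns < min_density * span:
                        continue
                    if strand == "-":
                        c0, c1 = len(cons) - c1, len(cons) - c0
                    frags.append(
                        {
                            "contig": contig,
                            "start": g0,
                            "end": g1,
                            "strand": strand,
                            "family": family,
                            "cons_start": c0,
                            "cons_end": c1,
                            "n_seeds": ns,
                        }
                    )
    if not frags:
        return pd.DataFrame(
            columns=[
                "contig", "start", "end", "strand", "family",
                "cons_start", "cons_end", "n_seeds",
            ]
        )
    df = pd.DataFrame(frags).sort_values(["contig", "start", "end"]).reset_index(drop=True)

    # resolve overlapping assignments to the single best family
    keep = []
    for _, group in df.groupby("contig", sort=False):
        rows = group.to_dict("records")
        rows.sort(key=lambda r: (r["start"], r["end"]))
        active: list[dict] = []
        for r in rows:
            drop = False
            for a in list(active):
                if a["end"] <= r["start"]:
                    active.remove(a)
                    continue
                overlap = min(a["end"], r["end"]) - max(a["start"], r["start"])
                if overlap <= 0.5 * min(a["end"] - a["start"], r["end"] - r["start"]):
                    continue
                if r["n_seeds"] == a["n_seeds"] and r["family"] != a["family"]:
                    log.info(
                        "tie at %s:%d between %s and %s resolved alphabetically",
                        r["contig"], r["start"], a["family"], r["family"],
                    )
                if (-r["n_seeds"], r["family"]) < (-a["n_seeds"], a["family"]):
                    keep.remove(a)
                    active.remove(a)
                else:
                    drop = True
                    break
            if not drop:
                keep.append(r)
                active.append(r)
    df = pd.DataFrame(keep).sort_values(["contig", "start"]).reset_index(drop=True)

    # merge nearby fragments of the same family/strand
    merged = []
    for (_, fam, strand), group in df.groupby(["contig", "family", "strand"], sort=False):
        rows = group.sort_values("start").to_dict("records")
        cur = rows[0]
        for r in rows[1:]:
            if r["start"] - cur["end"] <= merge_distance:
                cur["end"] = max(cur["end"], r["end"])
                cur["cons_start"] = min(cur["cons_start"], r["cons_start"])
                cur["cons_end"] = max(cur["cons_end"], r["cons_end"])
                cur["n_seeds"] += r["n_seeds"]
            else:
                merged.append(cur)
                cur = r
        merged.append(cur)
    return pd.DataFrame(merged).sort_values(["contig", "start"]).reset_index(drop=True)


def family_copy_numbers(
    genome: dict[str, str],
    library: dict[str, ConsensusEntry],
    **scan_kwargs,
) -> list[CopyNumberRecord]:
    """Total genomic fragment counts per family (zero-hit families included)."""
    frags = assign_fragments(genome, library, **scan_kwargs)
    records = []
    for family in sorted(library):
        sub = frags[frags.family == family] if len(frags) else frags
        records.append(
            CopyNumberRecord(
                family=family,
                n_total=int(len(sub)),
                fragments=sub.to_dict("records") if len(frags) else [],
            )
        )
    return records


def full_length_estimates(
    elements: list,
    copy_records: list[CopyNumberRecord],
    library: dict[str, ConsensusEntry],
    utr_margin: int = 50,
    min_element_identity: float = 0.60,
) -> list[CopyNumberRecord]:
    """Fill the two full-length copy-number estimates.

    n_fl_utr counts genomic fragments that reach the family consensus 5'
    end (within `utr_margin` bp): since reverse transcription starts at the
    3' end, a retained 5'UTR implies the insertion produced a complete
    element. n_fl_complete counts harvested FullLengthElements assigned (by
    best consensus identity) to the family whose 5'UTR region retains the
    very 5' head of the family promoter — i.e. elements with a complete
    5'UTR, as 5'-truncated copies never carry it. The ordering
    n_fl_complete <= n_fl_utr <= n_total is asserted.
    """
    from ._align import best_infix  # local import to keep module top light

    by_family = {r.family: r for r in copy_records}
    orphans = []
    assigned: dict[str, int] = {fam: 0 for fam in by_family}
    # elements are reconciled against the fragment table so that the two FL
    # estimates count through the same assignment
    frag_index: dict[str, list[dict]] = {}
    for rec in copy_records:
        for fr in rec.fragments:
            frag_index.setdefault(fr["contig"], []).append(fr)
    for e in elements:
        best_fr, best_ov = None, 0
        for fr in frag_index.get(e.contig, []):
            ov = min(fr["end"], e.end) - max(fr["start"], e.start)
            if ov > best_ov:
                best_fr, best_ov = fr, ov
        if best_fr is None:
            orphans.append(e.element_id)
            continue
        fam = best_fr["family"]
        if best_fr["cons_start"] > library[fam].feature_spans.get("5UTR", (0, 0))[0] + utr_margin:
            continue  # the insert's fragment does not reach the promoter head
        spans = library[fam].feature_spans
        utr_s, utr_e = spans.get("5UTR", (0, 0))
        head = library[fam].sequence[utr_s : min(utr_s + 100, utr_e)]
        utr_region = e.feature_sequence("5UTR")
        hit = best_infix(head, utr_region) if head and utr_region else None
        if hit is not None and hit.identity >= min_element_identity:
            assigned[fam] += 1
    if orphans:
        raise ValueError(
            "elements match no library family: " + ", ".join(sorted(orphans))
        )
    out = []
    for fam in sorted(by_family):
        rec = by_family[fam]
        utr_start = library[fam].feature_spans.get("5UTR", (0, 0))[0]
        n_utr = sum(
            1 for fr in rec.fragments if fr["cons_start"] <= utr_start + utr_margin
        )
        rec = CopyNumberRecord(
            family=fam,
            n_total=rec.n_total,
            n_fl_utr=n_utr,
            n_fl_complete=assigned[fam],
            fragments=rec.fragments,
        )
        rec.check()
        out.append(rec)
    return out


def copy_numbers_to_frame(records: list[CopyNumberRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "n_total": r.n_total,
                "n_fl_utr": r.n_fl_utr,
                "n_fl_complete": r.n_fl_complete,
            }
            for r in records
        ],
        columns=["family", "n_total", "n_fl_utr", "n_fl_complete"],
    )


# ---------------------------------------------------------------------------
# tandem repeats in promoters
# ---------------------------------------------------------------------------


def detect_tandem_repeats(
    promoter: str,
    min_unit: int = 10,
    min_copies: float = 2.0,
    min_identity: float = 0.8,
    max_unit: int = 300,
) -> list[RepeatArray]:
    """Periodicity scan for tandem arrays in a promoter sequence.

    For each candidate period p the self-match profile seq[i] == seq[i+p]
    is smoothed over p-length windows; maximal regions above `min_identity`
    define arrays, reported with a majority-rule unit consensus. Harmonic
    re-detections (arrays whose period is a multiple of an already accepted
    overlapping array's) are suppressed.
    """
    L = len(promoter)
    if L < 2 * min_unit:
        raise ValueError(f"promoter shorter than 2 x min_unit ({min_unit})")
    codes = encode_dna(promoter)
    found: list[RepeatArray] = []
    for p in range(min_unit, min(max_unit, L // 2) + 1):
        eq = (codes[:-p] == codes[p:]) & (codes[:-p] < 4)
        if eq.size < p:
            break
        c = np.concatenate([[0], np.cumsum(eq)])
        frac = (c[p:] - c[:-p]) / p  # match fraction of window [i, i+p)
        above = frac >= min_identity
        if not above.any():
            continue
        idx = np.nonzero(above)[0]
        breaks = np.nonzero(np.diff(idx) > p)[0]
        starts = [idx[0]] + [idx[b + 1] for b in breaks]
        ends = [idx[b] for b in breaks] + [idx[-1]]
        for s, e in zip(starts, ends):
            # the array covers both copies of every matching offset; trim
            # chance matches at the edges back to exact-match boundaries
            lo, hi = int(s), int(e) + p  # bounds in eq coordinates
            run = 5
            while lo < hi - run and not eq[lo : lo + run].all():
                lo += 1
            while hi - run > lo and not eq[hi - run : hi].all():
                hi -= 1
            span = (lo, hi + p)
            copies = (span[1] - span[0]) / p
            if copies < min_copies:
                continue
            redundant = False
            for prev in found:
                overlap = min(prev.end, span[1]) - max(prev.start, span[0])
                if overlap > 0.5 * (span[1] - span[0]) and (
                    abs(p - round(p / prev.unit_length) * prev.unit_length) <= 2
                    and p >= prev.unit_length
                ):
                    redundant = True
                    break
            if redundant:
                continue
            pieces = [
                promoter[i : i + p]
                for i in range(span[0], span[1] - p + 1, p)
            ]
            unit = _majority(pieces) if len(pieces) > 1 else pieces[0]
            found.append(
                RepeatArray(
                    unit_length=p,
                    copies=round(copies, 2),
                    start=span[0],
                    end=min(span[1], L),
                    unit=unit,
                )
            )
    found.sort(key=lambda r: (r.start, r.unit_length))
    return found


def _majority(pieces: list[str]) -> str:
    mat = np.array([list(s) for s in pieces if len(s) == len(pieces[0])])
    out = []
    for c in range(mat.shape[1]):
        col = mat[:, c]
        counts = {b: int((col == b).sum()) for b in "ACGT"}
        out.append(max("ACGT", key=lambda b: (counts[b], -ord(b))))
    return "".join(out)


def gc_content(seq: str) -> float:
    codes = encode_dna(seq)
    valid = codes < 4
    if not valid.any():
        return math.nan
    return float(((codes == 1) | (codes == 2))[valid].sum() / valid.sum())


# ---------------------------------------------------------------------------
# ORF1 LPR motif matrix
# ---------------------------------------------------------------------------

LPR_MOTIF_IDS = ("21bp", "33bp", "3bp", "9bp")


def lpr_motif_matrix(
    consensus_set: dict[str, str],
    motif_defs: dict[str, tuple[str, int]],
    ancestral: str,
    min_coverage: float = 0.8,
    min_identity: float = 0.8,
) -> pd.DataFrame:
    """Presence/absence of LPR motifs across aligned ORF1-region consensuses.

    `motif_defs` maps motif id -> (motif sequence, start in the *ungapped*
    ancestral consensus). A motif is present in a family when >=
    `min_coverage` of its columns are non-gap and the non-gap bases match
    the motif at >= `min_identity`. Rows with an entirely gapped motif
    region are flagged "unknown". The ancestral row is present for every
    motif by construction.
    """
    if ancestral not in consensus_set:
        raise ValueError(f"ancestral consensus {ancestral!r} not in set")
    aln_len = {len(s) for s in consensus_set.values()}
    if len(aln_len) != 1:
        raise ValueError("consensus sequences must be aligned to equal length")
    anc_row = consensus_set[ancestral].upper()
    col_of = [i for i, ch in enumerate(anc_row) if ch != "-"]
    motif_cols = {}
    for mid, (mseq, mstart) in motif_defs.items():
        if mstart + len(mseq) > len(col_of):
            raise ValueError(f"motif {mid} extends past the ancestral consensus")
        motif_cols[mid] = [col_of[mstart + j] for j in range(len(mseq))]
    all_cols = sorted({c for cols in motif_cols.values() for c in cols})
    rows = {}
    for name, seq in consensus_set.items():
        seq = seq.upper()
        if all(seq[c] == "-" for c in all_cols):
            rows[name] = {mid: "unknown" for mid in motif_defs}
            continue
        row = {}
        for mid, (mseq, _) in motif_defs.items():
            cols = motif_cols[mid]
            chars = [seq[c] for c in cols]
            nongap = [(ch, m) for ch, m in zip(chars, mseq.upper()) if ch != "-"]
            coverage = len(nongap) / len(cols)
            if coverage < min_coverage:
                row[mid] = "absent"
                continue
            ident = sum(1 for ch, m in nongap if ch == m) / len(nongap)
            row[mid] = "present" if ident >= min_identity else "absent"
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(motif_defs))
    return df.loc[list(consensus_set)]


# ---------------------------------------------------------------------------
# counting-based dN/dS (Nei-Gojobori 1986)
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Mutations to stop codons are excluded from the possible changes (the
    original counting convention, coherent with coding sequence whose
    frames stay open); the remainder scales to 3 sites per codon."""
    syn = 0.0
    total = 0.0
    aa = _AA[codon]
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in _STOPS:
                continue
            total += 1
            if _AA[alt] == aa:
                syn += 1
    syn_sites = 3.0 * syn / total if total else 0.0
    return syn_sites, 3.0 - syn_sites


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two sense codons; pathways through stop codons are skipped."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:  # all pathways blocked: count every step nonsynonymous
        return 0.0, float(len(diff_pos))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def _jc_correct(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan
    return -0.75 * math.log(arg)


def _pair_dnds(a: str, b: str) -> tuple[float, float] | None:
    S = N = sd = nd = 0.0
    ncod = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if c1 in _STOPS or c2 in _STOPS or c1 not in _AA or c2 not in _AA:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        dsd, dnd = _pair_differences(c1, c2)
        sd += dsd
        nd += dnd
        ncod += 1
    if ncod == 0 or S == 0 or N == 0:
        return None
    ds = _jc_correct(sd / S)
    dn = _jc_correct(nd / N)
    if math.isnan(ds) or math.isnan(dn):
        return None
    return dn, ds


def global_dnds(
    codon_alignment: dict[str, str] | list[str],
    on_stop: str = "exclude",
) -> OmegaEstimate:
    """Global Nei-Gojobori dN/dS over all sequence pairs of a codon alignment.

    By default sequences with premature in-frame stop codons are excluded
    with a warning (`on_stop="exclude"`); with `on_stop="mask"` offending
    codons are simply skipped per pair, which suits consensus sequences
    whose occasional majority-call errors produce isolated stops. Codons
    containing gaps or ambiguity are always skipped per pair. omega is None
    (undefined) when ds = 0.
    """
    if on_stop not in ("exclude", "mask"):
        raise ValueError("on_stop must be 'exclude' or 'mask'")
    seqs = (
        list(codon_alignment.values())
        if isinstance(codon_alignment, dict)
        else list(codon_alignment)
    )
    names = (
        list(codon_alignment.keys())
        if isinstance(codon_alignment, dict)
        else [str(i) for i in range(len(seqs))]
    )
    if any(len(s) % 3 for s in seqs):
        raise ValueError("alignment length must be divisible by 3")
    kept, kept_names = [], []
    for nm, s in zip(names, seqs):
        s = s.upper()
        codons = [s[i : i + 3] for i in range(0, len(s) - 3, 3)]  # last codon may stop
        if on_stop == "exclude" and any(c in _STOPS for c in codons):
            log.warning("sequence %s excluded: premature stop codon", nm)
            continue
        kept.append(s)
        kept_names.append(nm)
    if len(kept) < 2:
        raise ValueError("fewer than two stop-free sequences")
    dns, dss = [], []
    for a, b in itertools.combinations(kept, 2):
        got = _pair_dnds(a, b)
        if got is not None:
            dns.append(got[0])
            dss.append(got[1])
    if not dns:
        raise ValueError("no comparable sequence pairs")
    dn, ds = float(np.mean(dns)), float(np.mean(dss))
    return OmegaEstimate(dn=dn, ds=ds, omega=(dn / ds if ds > 0 else None))
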