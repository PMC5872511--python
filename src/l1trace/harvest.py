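"""Recovery of full-length L1 candidates from a genome.

The search anchors on the reverse-transcriptase (RT) domain of ORF2: a
six-frame translated search of the genome with a protein query (seeded
word matches extended by local Smith-Waterman under BLOSUM62), mirroring
the tBLASTn-style harvest used for real assemblies. Around each RT hit a
+/-7000 bp fragment is cut and annotated by nucleotide motif alignment
against ORF1 / ORF2 / 3'UTR exemplars; a candidate is called full length
only when all three are found in order. The 5'UTR is taken as the sequence
upstream of ORF1 within the element — no promoter homology is required,
since promoters turn over between lineages.

Coordinates are 0-based half-open on the forward strand of the contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._align import best_infix, revcomp

log = logging.getLogger(__name__)

SEED_WORD = 4  # amino acids
DEFAULT_FLANK = 7000
DEFAULT_UPSTREAM = 3000
#: maximum 5'UTR length assumed when delimiting the element upstream of ORF1
DEFAULT_MAX_UTR = 2500
#: fraction of the query self-score required to call an RT hit; calibrated on
#: simulation so that a 30%-diverged RT domain is still detected while
#: element-free random genomes yield nothing (see tests).
MIN_SCORE_FRACTION = 0.35
#: minimum edit identity for a motif exemplar to be called present
MOTIF_MIN_IDENTITY = 0.60
#: ORF motifs may match over a 3'-anchored fraction of the exemplar, admitting
#: near-full-length elements
MOTIF_MIN_FRACTION = 0.60


@dataclass
class ElementHit:
    contig: str
    rt_start: int
    rt_end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.rt_start >= self.rt_end:
            raise ValueError("rt_start must be < rt_end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class FullLengthElement:
    element_id: str
    contig: str
    start: int
    end: int
    strand: str
    feature_spans: dict[str, tuple[int, int]]  # element-local coordinates
    upstream_context: str
    sequence: str
    clipped: bool = False

    def feature_sequence(self, name: str) -> str:
        s, e = self.feature_spans[name]
        return self.sequence[s:e]


@dataclass
class Rejection:
    hit: ElementHit
    missing: list[str] = field(default_factory=list)
    reason: str = ""


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def _self_score(query: str) -> float:
    al = _aligner()
    return float(al.score(query, query))


def _translations(seq: str) -> list[tuple[str, int, str]]:
    """(strand, frame, translation) for all six frames."""
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append((strand, frame, str(Seq(sub).translate())))
    return out


def _seed_clusters(query: str, frame_aa: str) -> list[tuple[int, int]]:
    """Diagonal-clustered seed matches; returns [(t_lo, t_hi)] in aa coords."""
    words: dict[str, list[int]] = {}
    for i in range(len(query) - SEED_WORD + 1):
        words.setdefault(query[i : i + SEED_WORD], []).append(i)
    hits = []  # (diag, tpos)
    for t in range(len(frame_aa) - SEED_WORD + 1):
        qs = words.get(frame_aa[t : t + SEED_WORD])
        if qs:
            for q in qs:
                hits.append((t - q, t))
    if not hits:
        return []
    hits.sort()
    clusters: list[list[tuple[int, int]]] = []
    for diag, t in hits:
        placed = False
        for cl in clusters:
            d0, _ = cl[-1]
            if abs(diag - d0) <= 15 and abs(t - cl[-1][1]) <= len(query) + 30:
                cl.append((diag, t))
                placed = True
                break
        if not placed:
            clusters.append([(diag, t)])
    out = []
    for cl in clusters:
        if len(cl) < 2:
            continue
        ts = [t for _, t in cl]
        out.append((min(ts), max(ts) + SEED_WORD))
    # merge overlapping candidate windows
    out.sort()
    merged: list[list[int]] = []
    for lo, hi in out:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def scan_rt_hits(
    genome: dict[str, str],
    rt_query: str,
    min_score: float | None = None,
) -> list[ElementHit]:
    """Six-frame translated local-alignment search for the RT domain.

    Overlapping hits are merged keeping the best score; output is ordered by
    (contig, start). `min_score` defaults to MIN_SCORE_FRACTION of the
    query's self-alignment score.
    """
    rt_query = rt_query.strip().upper()
    if not rt_query:
        raise ValueError("empty RT query")
    if not genome:
        raise ValueError("empty genome")
    if min_score is None:
        min_score = MIN_SCORE_FRACTION * _self_score(rt_query)
    al = _aligner()
    qlen = len(rt_query)
    raw: list[ElementHit] = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        L = len(seq)
        for strand, frame, aa in _translations(seq):
            for lo, hi in _seed_clusters(rt_query, aa):
                w_lo = max(lo - qlen - 20, 0)
                w_hi = min(hi + qlen + 20, len(aa))
                window = aa[w_lo:w_hi]
                alns = al.align(rt_query, window)
                if len(alns) == 0:
                    continue
                best = alns[0]
                if best.score < min_score:
                    continue
                t0 = w_lo + int(best.aligned[1][0][0])
                t1 = w_lo + int(best.aligned[1][-1][1])
                nt0, nt1 = frame + 3 * t0, frame + 3 * t1
                if strand == "-":
                    nt0, nt1 = L - nt1, L - nt0
                raw.append(
                    ElementHit(
                        contig=contig,
                        rt_start=nt0,
                        rt_end=nt1,
                        strand=strand,
                        score=float(best.score),
                    )
                )
    # merge overlapping hits (any frame/strand), keeping the best score
    raw.sort(key=lambda h: (h.contig, h.rt_start, -h.score))
    merged: list[ElementHit] = []
    for h in raw:
        if (
            merged
            and merged[-1].contig == h.contig
            and h.rt_start < merged[-1].rt_end
        ):
            if h.score > merged[-1].score:
                merged[-1] = h
            continue
        merged.append(h)
    return merged


def fragment_bounds(
    hit: ElementHit, contig_length: int, flank: int = DEFAULT_FLANK
) -> tuple[int, int, bool]:
    """(lo, hi, clipped) of the +/-flank fragment around an RT hit, clipped
    at the contig bounds."""
    lo = max(hit.rt_start - flank, 0)
    hi = min(hit.rt_end + flank, contig_length)
    clipped = (hit.rt_start - flank < 0) or (hit.rt_end + flank > contig_length)
    return lo, hi, clipped


def assemble_full_length(
    hit: ElementHit,
    genome: dict[str, str],
    motif_library: dict[str, str],
    flank: int = DEFAULT_FLANK,
    upstream: int = DEFAULT_UPSTREAM,
    max_utr: int = DEFAULT_MAX_UTR,
    min_identity: float = MOTIF_MIN_IDENTITY,
    min_fraction: float = MOTIF_MIN_FRACTION,
) -> FullLengthElement | Rejection:
    """Cut a +/-`flank` bp fragment around an RT hit, annotate ORF1/ORF2/3'UTR
    by motif alignment and return a FullLengthElement when all are present
    in order (a Rejection naming the missing features otherwise)."""
    if hit.contig not in genome:
        raise ValueError(f"contig {hit.contig!r} not in genome")
    contig_seq = genome[hit.contig].upper()
    L = len(contig_seq)
    if not (0 <= hit.rt_start < hit.rt_end <= L):
        raise ValueError("hit coordinates outside the contig")
    frag_lo, frag_hi, clipped = fragment_bounds(hit, L, flank)
    fragment = contig_seq[frag_lo:frag_hi]
    if hit.strand == "-":
        fragment = revcomp(fragment)
        rt_lo = frag_hi - hit.rt_end
        rt_hi = frag_hi - hit.rt_start
    else:
        rt_lo = hit.rt_start - frag_lo
        rt_hi = hit.rt_end - frag_lo

    def find(name: str, window: tuple[int, int]) -> tuple[int, int] | None:
        exemplar = motif_library.get(name, "")
        if not exemplar:
            return None
        lo = max(window[0], 0)
        sub = fragment[lo : window[1]]
        found = best_infix(exemplar, sub)
        if found is None or found.identity < min_identity:
            # truncation is 5'-only: retry with a 3'-anchored partial exemplar
            part = exemplar[int(len(exemplar) * (1 - min_fraction)) :]
            found = best_infix(part, sub)
            if found is None or found.identity < min_identity:
                return None
        return (lo + found.start, lo + found.end)

    # anchor the annotation to THIS element: ORF2 must overlap the RT hit,
    # ORF1 lies upstream of ORF2, the 3'UTR downstream (fragments may contain
    # pieces of neighbouring inserts)
    spans: dict[str, tuple[int, int]] = {}
    missing: list[str] = []
    orf2_ex = len(motif_library.get("ORF2", ""))
    got = find("ORF2", (rt_lo - orf2_ex - 500, rt_hi + orf2_ex + 500))
    if got is None:
        missing.append("ORF2")
    else:
        spans["ORF2"] = got
        orf1_ex = len(motif_library.get("ORF1", ""))
        utr3_ex = len(motif_library.get("3UTR", ""))
        got1 = find("ORF1", (got[0] - orf1_ex - 1500, got[0] + 30))
        if got1 is None:
            missing.append("ORF1")
        else:
            spans["ORF1"] = got1
        got3 = find("3UTR", (got[1] - 30, got[1] + utr3_ex + 1500))
        if got3 is None:
            missing.append("3UTR")
        else:
            spans["3UTR"] = got3
    if missing:
        return Rejection(hit=hit, missing=missing, reason="motifs not detected")
    if not (spans["ORF1"][0] < spans["ORF2"][0] < spans["3UTR"][0]) or not (
        spans["ORF1"][1] <= spans["ORF2"][0] + 30
        and spans["ORF2"][1] <= spans["3UTR"][0] + 30
    ):
        return Rejection(hit=hit, missing=[], reason="features out of order")

    orf1_s = spans["ORF1"][0]
    el_lo = max(orf1_s - max_utr, 0)
    # the upstream window may contain the 3' tail of a neighbouring insert;
    # anything matching a body/3'UTR motif (either strand) upstream of ORF1
    # is not promoter, so the element start is clipped past it
    upstream_seq = fragment[el_lo:orf1_s]
    for name in ("3UTR", "ORF2", "ORF1"):
        exemplar = motif_library.get(name, "")
        probes = [exemplar, revcomp(exemplar)] if exemplar else []
        for probe in probes:
            probe = probe[-1000:] if name != "3UTR" else probe
            found = best_infix(probe, upstream_seq)
            if found is not None and found.identity >= min_identity:
                el_lo = el_lo + found.end
                upstream_seq = fragment[el_lo:orf1_s]
    el_hi = spans["3UTR"][1]
    local = {
        "5UTR": (0, orf1_s - el_lo),
        "ORF1": (spans["ORF1"][0] - el_lo, spans["ORF1"][1] - el_lo),
        "IGR": (spans["ORF1"][1] - el_lo, spans["ORF2"][0] - el_lo),
        "ORF2": (spans["ORF2"][0] - el_lo, spans["ORF2"][1] - el_lo),
        "3UTR": (spans["3UTR"][0] - el_lo, spans["3UTR"][1] - el_lo),
    }
    sequence = fragment[el_lo:el_hi]
    # map element-forward fragment coordinates back to the contig
    if hit.strand == "+":
        g_start, g_end = frag_lo + el_lo, frag_lo + el_hi
        up_lo = max(g_start - upstream, 0)
        upstream_ctx = contig_seq[up_lo:g_start]
    else:
        g_start = frag_hi - el_hi
        g_end = frag_hi - el_lo
        up_hi = min(g_end + upstream, L)
        upstream_ctx = revcomp(contig_seq[g_end:up_hi])
    return FullLengthElement(
        element_id=f"el_{hit.contig}_{g_start}_{hit.strand}",
        contig=hit.contig,
        start=g_start,
        end=g_end,
        strand=hit.strand,
        feature_spans=local,
        upstream_context=upstream_ctx,
        sequence=sequence,
        clipped=bool(clipped),
    )


def write_elements(elements: list[FullLengthElement], fasta_path, table_path) -> None:
    """Elements as FASTA plus a TSV feature table (1-based inclusive spans in
    the human-readable table; element-local)."""
    import pandas as pd

    with open(fasta_path, "w") as fh:
        for e in elements:
            fh.write(f">{e.element_id}\n{e.sequence}\n")
    columns = ["element_id", "contig", "start", "end", "strand", "clipped",
               "upstream_context"]
    for name in ("5UTR", "ORF1", "IGR", "ORF2", "3UTR"):
        columns += [f"{name}_first", f"{name}_last"]
    rows = []
    for e in elements:
        row = {
            "element_id": e.element_id,
            "contig": e.contig,
            "start": e.start,
            "end": e.end,
            "strand": e.strand,
            "clipped": e.clipped,
            "upstream_context": e.upstream_context,
        }
        for name, (s, ee) in e.feature_spans.items():
            row[f"{name}_first"] = s + 1
            row[f"{name}_last"] = ee
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(table_path, sep="\t", index=False)


def read_elements(fasta_path, table_path) -> list[FullLengthElement]:
    import pandas as pd
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    df = pd.read_csv(table_path, sep="\t", keep_default_na=False)
    for _, row in df.iterrows():
        spans = {}
        for name in ("5UTR", "ORF1", "IGR", "ORF2", "3UTR"):
            if f"{name}_first" in row:
                spans[name] = (int(row[f"{name}_first"]) - 1, int(row[f"{name}_last"]))
        out.append(
            FullLengthElement(
                element_id=row["element_id"],
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                feature_spans=spans,
                upstream_context=str(row.get("upstream_context", "") or ""),
                sequence=seqs[row["element_id"]],
                clipped=bool(row.get("clipped", False)),
            )
        )
    return out


def harvest_genome(
    genome: dict[str, str],
    rt_query: str,
    motif_library: dict[str, str],
    min_score: float | None = None,
    **assemble_kwargs,
) -> tuple[list[FullLengthElement], list[Rejection]]:
    """Scan for RT hits and assemble full-length candidates around each."""
    elements, rejections = [], []
    hits = scan_rt_hits(genome, rt_query, min_score=min_score) if genome else []
    for hit in hits:
        got = assemble_full_length(hit, genome, motif_library, **assemble_kwargs)
        if isinstance(got, FullLengthElement):
            elements.append(got)
        else:
            rejections.append(got)
            log.info(
                "rejected hit %s:%d-%d (%s): missing %s",
                hit.contig,
                hit.rt_start,
                hit.rt_end,
                got.reason,
                ",".join(got.missing) or "-",
            )
    return elements, rejections
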