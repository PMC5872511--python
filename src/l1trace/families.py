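"""Classification of full-length elements into families.

Families are diagnosed in two steps, mirroring how L1 lineages are
recognised in mammalian genomes: (1) elements are grouped by 5'UTR
homology — promoter turnover makes the 5'UTR the coarsest lineage marker —
then (2) each promoter class is split into families by neighbor-joining
clustering of the 3'-terminus region (end of ORF2 + 3'UTR) under a
TN93-corrected distance, cutting the bootstrap-annotated tree where a
well-supported split separates groups whose within-group divergence is
small relative to the divergence across the split. Candidate families are
re-checked for compatibility on a 5'-promoter-region tree, and clusters
below the minimum copy number are dropped (only families with >10
full-length or near-full-length copies support a reliable consensus).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from ._align import align_sequences, best_infix
from ._trees import Node, neighbor_joining, newick, split_support, splits
from ._align import encode_dna

log = logging.getLogger(__name__)

MIN_FAMILY_SIZE = 10  # "> 10 copies" inclusion rule for families


@dataclass
class PromoterClass:
    class_id: int
    exemplar: str
    members: list[str]  # element ids


@dataclass
class FamilyRecord:
    name: str
    promoter_type: int
    members: list[str]
    consensus: str
    n_members: int
    consensus_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    promoter_tree_compatible: bool = True
    tree_newick: str = ""


# ---------------------------------------------------------------------------
# promoter classification
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def promoter_identity(a: str, b: str, k: int = 11) -> tuple[float, float]:
    """(identity, coverage-of-shorter) for the shared promoter block.

    The homologous block on the shorter sequence is chained from its 3' end
    (the promoter abuts ORF1; stray homology further upstream belongs to
    flanking sequence, not the promoter) using k-mers shared with the longer
    one; identity is the block's edit identity as an infix of the longer.
    Non-homologous promoters share essentially no k-mers and score ~0 on
    both axes.
    """
    if len(a) > len(b):
        a, b = b, a
    if not a:
        return 0.0, 0.0
    box = _promoter_block(a, b, k=k)
    if box is None:
        return 0.0, 0.0
    block = a.upper()[box[0] : box[1]]
    found = best_infix(block, b)
    if found is None:
        return 0.0, 0.0
    return found.identity, len(block) / len(a)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def classify_promoters(
    elements: list,
    identity_threshold: float = 0.70,
    coverage_threshold: float = 0.50,
    k: int = 11,
) -> tuple[list[PromoterClass], list[str]]:
    """Single-linkage grouping of elements by 5'UTR homology.

    Two elements link when their promoter identity is >= identity_threshold
    over >= coverage_threshold of the shorter 5'UTR. Classes are numbered by
    descending member count (1-based). Elements with an empty 5'UTR go to
    the returned unclassified list rather than erroring.
    """
    utrs, ids = [], []
    unclassified = []
    for e in elements:
        utr = e.feature_sequence("5UTR")
        if not utr:
            unclassified.append(e.element_id)
        else:
            utrs.append(utr.upper())
            ids.append(e.element_id)
    n = len(utrs)
    uf = _UnionFind(n)
    ksets = [_kmer_set(u, k) for u in utrs]
    for i, j in itertools.combinations(range(n), 2):
        if uf.find(i) == uf.find(j):
            continue
        if len(ksets[i] & ksets[j]) < 3:  # cheap non-homology screen
            continue
        ident, cov = promoter_identity(utrs[i], utrs[j], k=k)
        if ident >= identity_threshold and cov >= coverage_threshold:
            uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), ids[g[0]]))
    classes = []
    for cid, grp in enumerate(ordered, start=1):
        # exemplar: the member sharing the most promoter sequence with the
        # class (window length is uninformative — truncated elements carry
        # full-size windows padded with genomic flank)
        sample = grp[:: max(1, len(grp) // 10)][:10]

        def block_total(i: int) -> int:
            total = 0
            for j in sample:
                if j == i:
                    continue
                box = _promoter_block(utrs[j], utrs[i], k=k)
                if box:
                    total += box[1] - box[0]
            return total

        exemplar_idx = max(grp, key=lambda i: (block_total(i), -i))
        classes.append(
            PromoterClass(
                class_id=cid,
                exemplar=utrs[exemplar_idx],
                members=[ids[i] for i in grp],
            )
        )
    return classes, unclassified


# ---------------------------------------------------------------------------
# family clustering on the 3' terminus
# ---------------------------------------------------------------------------


def _three_prime_region(element, region_len: int) -> str:
    end = element.feature_spans["3UTR"][1]
    return element.sequence[max(end - region_len, 0) : end]


def _distance_matrix(rows: np.ndarray) -> np.ndarray:
    from .chronology import tn93_matrix

    return tn93_matrix(rows)


def nj_with_bootstrap(
    rows: np.ndarray, names: list[str], reps: int, rng: np.random.Generator
) -> tuple[Node, list[Node], np.ndarray, list[str]]:
    """NJ tree on TN93 distances plus `reps` column-resampled bootstrap trees.

    Sequences producing saturated/undefined distances are dropped greedily
    (most-saturated first) and reported in the fourth return value."""
    D = _distance_matrix(rows)
    excluded: list[str] = []
    while np.isnan(D).any():
        worst = int(np.isnan(D).sum(axis=1).argmax())
        excluded.append(names[worst])
        keep = [i for i in range(len(names)) if i != worst]
        names = [names[i] for i in keep]
        rows = rows[keep]
        D = D[np.ix_(keep, keep)]
    if len(names) < 3:
        raise ValueError("fewer than three alignable sequences in region")
    tree = neighbor_joining(D, names)
    boots = []
    ncol = rows.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        Db = _distance_matrix(rows[:, cols])
        Db = np.nan_to_num(Db, nan=np.nanmax(Db[np.isfinite(Db)], initial=1.0))
        boots.append(neighbor_joining(Db, names))
    return tree, boots, D, excluded


def _mean_within(D: np.ndarray, idx: list[int]) -> float:
    if len(idx) < 2:
        return 0.0
    sub = D[np.ix_(idx, idx)]
    return float(sub[np.triu_indices(len(idx), 1)].mean())


def _mean_between(D: np.ndarray, a: list[int], b: list[int]) -> float:
    return float(D[np.ix_(a, b)].mean())


def _select_clades(
    all_leaves: frozenset,
    tree_splits: list[tuple[frozenset, float]],
    D: np.ndarray,
    pos: dict[str, int],
    support_threshold: float,
    within_between_ratio: float,
) -> tuple[list[frozenset], list[str]]:
    """Pick maximal well-supported clades that are internally homogeneous.

    A clade qualifies when its bootstrap support passes the threshold and
    its mean within-divergence is at most `within_between_ratio` times its
    mean divergence to everything outside it. Qualifying clades are chosen
    greedily, largest first, without overlap; if none qualifies the whole
    class is one family. Leaves covered by no chosen clade are returned as
    strays (they join no family and are dropped downstream).
    """
    supported = [
        (side, sup) for side, sup in tree_splits if sup >= support_threshold
    ]

    def refine(clade: frozenset) -> tuple[list[frozenset], list[str]]:
        candidates = []
        for side, _ in supported:
            # only supported tree clades strictly inside `clade` qualify
            if not side < clade or len(side) < 2:
                continue
            sub = side
            ia = [pos[x] for x in sorted(sub)]
            ib = [pos[x] for x in sorted(clade - sub)]
            between = _mean_between(D, ia, ib)
            within = _mean_within(D, ia)
            if between > 0 and within / between <= within_between_ratio:
                candidates.append((sub, within))
        if not candidates:
            return [clade], []
        candidates.sort(key=lambda c: (-len(c[0]), c[1], sorted(c[0])))
        chosen: list[frozenset] = []
        covered: set[str] = set()
        for side, _ in candidates:
            if side & covered:
                continue
            chosen.append(side)
            covered |= side
        out: list[frozenset] = []
        strays: list[str] = []
        for ch in chosen:
            # a chosen clade may itself be a union of tight families whose
            # mean divergence slipped under the ratio; refine recursively
            sub_clades, sub_strays = refine(ch)
            out.extend(sub_clades)
            strays.extend(sub_strays)
        leftover = frozenset(clade - covered)
        if len(leftover) >= 2 and leftover != clade:
            sub_clades, sub_strays = refine(leftover)
            out.extend(sub_clades)
            strays.extend(sub_strays)
        elif leftover:
            strays.extend(sorted(leftover))
        return out, strays

    return refine(frozenset(all_leaves))


def cluster_families(
    pclass: PromoterClass,
    elements: list,
    min_family_size: int = MIN_FAMILY_SIZE,
    bootstrap_reps: int = 1000,
    support_threshold: float = 70.0,
    within_between_ratio: float = 0.5,
    region_len: int = 600,
    promoter_region_len: int = 600,
    seed: int = 0,
) -> list[FamilyRecord]:
    """Split one promoter class into families on a 3'-terminus NJ tree.

    The bootstrap-annotated tree is cut recursively at supported splits
    (>= support_threshold) whose within/between divergence ratio is at most
    `within_between_ratio`; each resulting cluster below `min_family_size`
    is dropped (logged). Surviving families are re-checked on a 5'-promoter
    region tree: a family is flagged incompatible when its members are
    scattered (purity of the smallest containing clade < 0.5). Consensus
    sequences are column-majority over the aligned members.
    """
    rng = np.random.default_rng(seed)
    by_id = {e.element_id: e for e in elements}
    members = [by_id[eid] for eid in pclass.members if eid in by_id]
    if len(members) < min_family_size:
        raise ValueError(
            f"promoter class {pclass.class_id} has {len(members)} members "
            f"(< min_family_size {min_family_size})"
        )
    regions = {e.element_id: _three_prime_region(e, region_len) for e in members}
    aligned = align_sequences(regions)
    names = list(aligned)
    rows = np.stack([encode_dna(aligned[nm]) for nm in names])
    usable = [i for i in range(len(names)) if (rows[i] < 4).sum() >= 50]
    if len(usable) < len(names):
        dropped = set(range(len(names))) - set(usable)
        for i in sorted(dropped):
            log.warning("element %s excluded: no usable 3' region", names[i])
        names = [names[i] for i in usable]
        rows = rows[usable]
    tree, boots, D, excluded = nj_with_bootstrap(rows, names, bootstrap_reps, rng)
    for nm in excluded:
        log.warning("element %s excluded: saturated 3'-region distances", nm)
    names = [nm for nm in names if nm not in excluded]
    all_leaves = frozenset(names)
    tree_splits = [
        (side, split_support(side, all_leaves, boots)) for side in splits(tree)
    ]
    # both sides of every split are candidate clades
    tree_splits += [(all_leaves - side, sup) for side, sup in tree_splits]
    pos = {nm: i for i, nm in enumerate(names)}
    clades, strays = _select_clades(
        all_leaves, tree_splits, D, pos, support_threshold, within_between_ratio
    )
    for nm in strays:
        log.info("promoter class %d: element %s joins no family", pclass.class_id, nm)
    clusters = sorted((sorted(c) for c in clades), key=lambda c: (-len(c), c))

    # promoter-region verification tree
    prom_seqs = {
        e.element_id: e.feature_sequence("5UTR")[-promoter_region_len:]
        for e in members
        if e.element_id in pos
    }
    prom_aligned = align_sequences(prom_seqs)
    prom_rows = np.stack([encode_dna(prom_aligned[nm]) for nm in names])
    try:
        prom_tree = neighbor_joining(_distance_matrix(prom_rows), names)
        prom_sides = splits(prom_tree)
        prom_sides |= {all_leaves - s for s in prom_sides}
    except ValueError:
        prom_sides = set()

    records = []
    for ci, cluster in enumerate(clusters, start=1):
        if len(cluster) < min_family_size:
            log.info(
                "promoter class %d: dropping cluster of %d (< %d): %s",
                pclass.class_id,
                len(cluster),
                min_family_size,
                ",".join(cluster[:5]),
            )
            continue
        cset = frozenset(cluster)
        containing = [s for s in prom_sides if cset <= s]
        purity = (
            len(cset) / min(len(s) for s in containing) if containing else 1.0
        )
        consensus, spans = family_consensus(
            [by_id[eid] for eid in cluster], pclass.exemplar
        )
        records.append(
            FamilyRecord(
                name=f"cluster{pclass.class_id}.{ci}",
                promoter_type=pclass.class_id,
                members=cluster,
                consensus=consensus,
                n_members=len(cluster),
                consensus_spans=spans,
                promoter_tree_compatible=purity >= 0.5,
                tree_newick=newick(tree),
            )
        )
    return records


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def family_consensus(
    members: list,
    promoter_exemplar: str,
    full_coverage: float = 0.9,
    k: int = 11,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Family consensus stitched from a promoter part and a body part.

    The 5'UTR region of a harvested element contains genomic flank of
    unknowable extent (and 5'-truncated copies lack the promoter head
    entirely), so the promoter consensus is derived only from members whose
    5'UTR covers essentially the whole promoter-class exemplar; the body
    (ORF1 through 3'UTR) consensus uses every member. Feature spans are
    projected from the first member.
    """
    boxes: dict[str, tuple[str, tuple[int, int]]] = {}
    for e in members:
        utr = e.feature_sequence("5UTR").upper()
        if not utr:
            continue
        box = _promoter_block(utr, promoter_exemplar, k=k)
        if box is not None:
            boxes[e.element_id] = (utr, box)
    prom_members: dict[str, str] = {}
    if boxes:
        # the longest homologous block across members estimates the full
        # promoter length; members covering ~all of it are full length
        # there. The second-largest block is used so that the exemplar's
        # owner (whose self-comparison spans its whole window, flank
        # included) cannot inflate the estimate.
        lens = sorted((hi - lo for _, (lo, hi) in boxes.values()), reverse=True)
        plen = lens[1] if len(lens) > 1 else lens[0]
        prom_members = {
            eid: utr[lo:hi]
            for eid, (utr, (lo, hi)) in boxes.items()
            if hi - lo >= full_coverage * plen
        }
    if len(prom_members) >= 2:
        prom_cons = build_consensus(list(align_sequences(prom_members).values()))
    elif prom_members:
        prom_cons = next(iter(prom_members.values()))
    else:
        prom_cons = promoter_exemplar
    body = {
        e.element_id: e.sequence[e.feature_spans["ORF1"][0] :] for e in members
    }
    ref = members[0]
    shift = ref.feature_spans["ORF1"][0]
    ref_spans = {
        nm: (s - shift, e - shift)
        for nm, (s, e) in ref.feature_spans.items()
        if nm != "5UTR"
    }
    body_cons, body_spans = consensus_with_spans(
        align_sequences(body), ref_spans, ref.element_id, trim_low_agreement=False
    )
    consensus = prom_cons + body_cons
    off = len(prom_cons)
    spans = {"5UTR": (0, off)}
    spans.update({nm: (s + off, e + off) for nm, (s, e) in body_spans.items()})
    return consensus, spans


def _promoter_block(
    utr: str, exemplar: str, k: int = 11, max_gap: int = 100
) -> tuple[int, int] | None:
    """Span on `utr` of the promoter block homologous to the exemplar.

    The block is chained right-to-left from the promoter/ORF1 junction
    (breaking at homology gaps > `max_gap`), so stray homology in the
    genomic flank — e.g. the 3' tail of an upstream insert — does not
    inflate it."""
    kb = _kmer_set(exemplar.upper(), k)
    au = utr.upper()
    pos = [i for i in range(len(au) - k + 1) if au[i : i + k] in kb]
    if not pos:
        return None
    hi = pos[-1] + k
    lo = pos[-1]
    for i in reversed(pos[:-1]):
        if lo - i > max_gap:
            break
        lo = i
    return lo, hi


def build_consensus(aligned: list[str]) -> str:
    """Column-majority consensus of an alignment.

    Columns gapped in more than half the members are removed; among bases,
    ties break alphabetically (A < C < G < T). Deterministic.
    """
    if len(aligned) < 2:
        raise ValueError("need at least two aligned sequences")
    if len({len(s) for s in aligned}) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    cons, _, _ = _consensus_cols(aligned)
    return cons


def _consensus_cols(aligned: list[str]) -> tuple[str, list[int], list[float]]:
    """(consensus, kept alignment columns, per-column agreement fraction)."""
    mat = np.array([list(s.upper()) for s in aligned])
    n = mat.shape[0]
    out, kept, agree = [], [], []
    for c in range(mat.shape[1]):
        col = mat[:, c]
        gaps = int((col == "-").sum())
        if gaps * 2 > n:
            continue
        counts = {b: int((col == b).sum()) for b in "ACGT"}
        best = max("ACGT", key=lambda b: (counts[b], -ord(b)))
        if counts[best] == 0:
            continue
        out.append(best)
        kept.append(c)
        agree.append(counts[best] / n)
    return "".join(out), kept, agree


def consensus_with_spans(
    aligned: dict[str, str],
    reference_spans: dict[str, tuple[int, int]],
    reference_id: str,
    trim_low_agreement: bool = True,
    agreement_threshold: float = 0.6,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Consensus plus feature spans projected from a reference member.

    Harvested elements carry non-homologous genomic flank upstream of the
    promoter (the element 5' boundary is unknowable without promoter
    homology); flank columns have low member agreement, so the consensus 5'
    end is trimmed to the first sustained run of high-agreement columns
    (never past the ORF1 start)."""
    names = list(aligned)
    cons, kept, agree = _consensus_cols([aligned[nm] for nm in names])
    ref_row = aligned[reference_id]
    # reference local coord of each alignment column (position before column)
    ref_coord = np.cumsum([1 if ch != "-" else 0 for ch in ref_row])
    col_of_kept = np.asarray(kept)
    spans = {}
    for name, (s, e) in reference_spans.items():
        in_span = (ref_coord[col_of_kept] > s) & (ref_coord[col_of_kept] <= e)
        idx = np.nonzero(in_span)[0]
        spans[name] = (int(idx[0]), int(idx[-1]) + 1) if idx.size else (0, 0)
    if trim_low_agreement and len(cons) > 100:
        w = 50
        run = np.convolve(np.asarray(agree), np.ones(w) / w, mode="valid")
        good = np.nonzero(run >= agreement_threshold)[0]
        trim = int(good[0]) if good.size else 0
        trim = min(trim, spans.get("ORF1", (len(cons), 0))[0])
        if trim > 0:
            cons = cons[trim:]
            spans = {
                nm: (max(s - trim, 0), max(e - trim, 0)) for nm, (s, e) in spans.items()
            }
    return cons, spans


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def name_families(
    families: list[FamilyRecord],
    ages: dict[str, float],
    genome_labels: dict[str, str],
) -> list[FamilyRecord]:
    """Assign names L1_{Ec|Cs|Perissodactyla}{promoter#}_{Roman}.

    Shared families are labelled Perissodactyla. Roman numerals rank
    families of the same (genome label, promoter type) by ascending age
    (youngest = I); age ties break by descending copy number (logged). The
    result is a pure function of (label, promoter type, age rank): input
    order never changes names.
    """
    label_map = {"Ec": "Ec", "Cs": "Cs", "shared": "Perissodactyla"}
    keyed = []
    for fam in families:
        label = genome_labels[fam.name]
        if label not in label_map:
            raise ValueError(f"unknown genome label {label!r} for {fam.name}")
        if fam.name not in ages:
            raise ValueError(f"no age estimate for {fam.name}")
        keyed.append((label_map[label], fam.promoter_type, fam))
    out = []
    for (label, ptype), group in itertools.groupby(
        sorted(
            keyed,
            key=lambda t: (t[0], t[1], ages[t[2].name], -t[2].n_members, t[2].name),
        ),
        key=lambda t: (t[0], t[1]),
    ):
        fams = [t[2] for t in group]
        for rank, fam in enumerate(fams, start=1):
            if rank > 1 and ages[fam.name] == ages[fams[rank - 2].name]:
                log.info(
                    "age tie between %s and %s broken by copy number",
                    fams[rank - 2].name,
                    fam.name,
                )
            out.append(
                FamilyRecord(
                    name=f"L1_{label}{ptype}_{roman(rank)}",
                    promoter_type=fam.promoter_type,
                    members=fam.members,
                    consensus=fam.consensus,
                    n_members=fam.n_members,
                    consensus_spans=fam.consensus_spans,
                    promoter_tree_compatible=fam.promoter_tree_compatible,
                    tree_newick=fam.tree_newick,
                )
            )
    return out
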