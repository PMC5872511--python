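"""Forward simulation of LINE-1 amplification histories.

A scenario plants copies of one or more L1 families into a random background
genome. Each copy is drawn at an insertion time inside the family's
amplification window, accumulates neutral substitutions for that long
(equal-rate, Jukes-Cantor-style process, optionally elevated at CpG sites),
is 5'-truncated with probability 1 - p_full_length, and is placed on a
random strand at a uniform position. The emitted truth table gives every
downstream stage a known answer.

Coordinates are 0-based half-open; times are Myr before present; rates are
substitutions/site/Myr along a single lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import decode_dna, encode_dna, revcomp

FEATURES = ("5UTR", "ORF1", "IGR", "ORF2", "3UTR")

TRUTH_COLUMNS = [
    "insert_id",
    "family",
    "time_myr",
    "contig",
    "start",
    "end",
    "strand",
    "full_length",
    "trunc_bp",
]

#: per-lineage neutral substitution rate (substitutions/site/Myr) used
#: throughout: 0.13%/Myr, the calibrated perissodactyl L1 clock.
DEFAULT_RATE = 0.0013

#: fraction of insertions that are full length (~10% in rhinoceros families).
DEFAULT_P_FULL_LENGTH = 0.1

#: mean 5'-truncation length (bp) for truncated copies.
DEFAULT_TRUNCATION_SCALE = 2000.0

#: truncated copies lose at least this much of the 5' end, so "retains the
#: very 5' end" remains equivalent to "full length" (target-primed reverse
#: transcription either completes or aborts well short of the 5' end).
MIN_TRUNCATION = 100

#: at least this much of the 3' end always survives truncation.
MIN_RETAINED = 200


class SimulationSizeError(ValueError):
    """Genome too short to hold the requested inserts."""


@dataclass
class FamilySpec:
    """One amplifying family: a source (progenitor) sequence with annotated
    feature spans and an amplification window [t_end, t_start] in Myr."""

    name: str
    source_sequence: str
    feature_spans: dict[str, tuple[int, int]]
    promoter_type: int
    t_start: float
    t_end: float
    n_inserts: int
    p_full_length: float = DEFAULT_P_FULL_LENGTH
    truncation_scale: float = DEFAULT_TRUNCATION_SCALE

    def __post_init__(self) -> None:
        if not (self.t_start > self.t_end >= 0):
            raise ValueError(
                f"family {self.name}: need t_start > t_end >= 0, "
                f"got ({self.t_start}, {self.t_end})"
            )
        if not 0 <= self.p_full_length <= 1:
            raise ValueError(f"family {self.name}: p_full_length outside [0, 1]")
        s, e = self.feature_spans["5UTR"]
        if e <= s:
            raise ValueError(f"family {self.name}: empty promoter span")

    @property
    def length(self) -> int:
        return len(self.source_sequence)


@dataclass
class AmplificationScenario:
    families: list[FamilySpec]
    genome_length: int
    background_gc: float = 0.42
    rate_per_lineage: float = DEFAULT_RATE
    cpg_multiplier: float = 1.0
    seed: int = 0
    contig_name: str = "contig_1"

    def __post_init__(self) -> None:
        if self.rate_per_lineage < 0:
            raise ValueError("rate_per_lineage must be >= 0")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        total = sum(f.length * f.n_inserts for f in self.families)
        if self.genome_length <= total:
            raise SimulationSizeError(
                f"genome_length {self.genome_length} cannot hold "
                f"{total} bp of planted elements "
                f"(deficit {total - self.genome_length + 1} bp)"
            )


@dataclass
class TruthRecord:
    insert_id: str
    family_name: str
    insertion_time: float
    contig: str
    start: int
    end: int
    strand: str
    full_length: bool
    truncation_offset: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if (self.truncation_offset == 0) != self.full_length:
            raise ValueError("truncation_offset == 0 iff full_length")


# ---------------------------------------------------------------------------
# substitution process
# ---------------------------------------------------------------------------


def evolve_sequence(
    seq: str,
    t: float,
    rate: float,
    cpg_multiplier: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Accumulate t Myr of neutral substitutions on `seq`.

    Per-site substitution probability is the Jukes-Cantor closed form
    3/4 * (1 - exp(-4/3 * rate * t)); at sites inside a CpG dinucleotide of
    the input sequence the rate is multiplied by `cpg_multiplier`. Length is
    preserved; substituted bases are drawn uniformly from the other three.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    codes = encode_dna(seq)
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        raise ValueError(f"non-ACGT character {seq[bad[0]]!r} at position {bad[0]}")
    if t == 0 or rate == 0 or not seq:
        return seq.upper()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = np.full(len(seq), 0.75 * -np.expm1(-4.0 / 3.0 * rate * t))
    if cpg_multiplier != 1.0:
        cpg = np.zeros(len(seq), dtype=bool)
        is_c = codes[:-1] == 1
        is_g = codes[1:] == 2
        hit = is_c & is_g
        cpg[:-1] |= hit
        cpg[1:] |= hit
        p[cpg] = 0.75 * -np.expm1(-4.0 / 3.0 * rate * cpg_multiplier * t)
    sub = rng.random(len(seq)) < p
    shifts = rng.integers(1, 4, size=int(sub.sum()))
    codes = codes.copy()
    codes[sub] = (codes[sub] + shifts) % 4
    return decode_dna(codes)


# ---------------------------------------------------------------------------
# history simulation
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return decode_dna(rng.choice(4, size=n, p=probs).astype(np.uint8))


def _draw_truncation(rng: np.random.Generator, spec: FamilySpec) -> int:
    mean_extra = max(spec.truncation_scale - MIN_TRUNCATION, 1.0)
    trunc = MIN_TRUNCATION + int(rng.geometric(1.0 / mean_extra))
    return min(trunc, spec.length - MIN_RETAINED)


def simulate_history(
    scenario: AmplificationScenario,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate the scenario; returns ({contig: sequence}, truth table).

    Identical scenario + seed give byte-identical output. Placement is
    uniform over background positions and inserts never overlap (no nesting).
    """
    rng = np.random.default_rng(scenario.seed)
    pieces: list[dict] = []
    for spec in scenario.families:
        times = rng.uniform(spec.t_end, spec.t_start, size=spec.n_inserts)
        full = rng.random(spec.n_inserts) < spec.p_full_length
        for i in range(spec.n_inserts):
            trunc = 0 if full[i] else _draw_truncation(rng, spec)
            evolved = evolve_sequence(
                spec.source_sequence,
                float(times[i]),
                scenario.rate_per_lineage,
                scenario.cpg_multiplier,
                rng=rng,
            )
            retained = evolved[trunc:]
            strand = "+" if rng.random() < 0.5 else "-"
            pieces.append(
                {
                    "insert_id": f"{spec.name}_{i:04d}",
                    "family": spec.name,
                    "time_myr": float(times[i]),
                    "strand": strand,
                    "full_length": bool(full[i]),
                    "trunc_bp": int(trunc),
                    "seq": retained if strand == "+" else revcomp(retained),
                }
            )
    total_insert = sum(len(p["seq"]) for p in pieces)
    background_len = scenario.genome_length - total_insert
    if background_len <= len(pieces):
        raise SimulationSizeError(
            f"genome_length {scenario.genome_length} leaves only "
            f"{background_len} bp of background for {len(pieces)} inserts"
        )
    background = _random_dna(rng, background_len, scenario.background_gc)
    offsets = np.sort(rng.choice(background_len, size=len(pieces), replace=False))
    order = rng.permutation(len(pieces))
    rows = []
    chunks: list[str] = []
    cursor = 0  # background position consumed so far
    placed = 0  # genome position written so far
    for off, pi in zip(offsets, order):
        piece = pieces[pi]
        chunks.append(background[cursor:off])
        placed += off - cursor
        cursor = off
        start = placed
        chunks.append(piece["seq"])
        placed += len(piece["seq"])
        rows.append(
            {
                "insert_id": piece["insert_id"],
                "family": piece["family"],
                "time_myr": piece["time_myr"],
                "contig": scenario.contig_name,
                "start": start,
                "end": placed,
                "strand": piece["strand"],
                "full_length": piece["full_length"],
                "trunc_bp": piece["trunc_bp"],
            }
        )
    chunks.append(background[cursor:])
    genome = {scenario.contig_name: "".join(chunks)}
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
    return genome, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the truth table as TSV with the fixed column header."""
    out = truth.copy() if len(truth) else pd.DataFrame(columns=TRUTH_COLUMNS)
    out = out[TRUTH_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "insert_id": str,
            "family": str,
            "contig": str,
            "strand": str,
            "start": int,
            "end": int,
            "trunc_bp": int,
            "full_length": bool,
            "time_myr": float,
        },
    )
    return df[TRUTH_COLUMNS]


def write_genome_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# synthetic sources and ready-made scenarios
# ---------------------------------------------------------------------------

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: local span of the reverse-transcriptase domain inside ORF2 (bp).
RT_OFFSET = 1200
RT_LENGTH = 750


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n_codons))


def synthetic_l1_source(
    rng: np.random.Generator,
    promoter: str | None = None,
    utr5_len: int = 2000,
    orf1_len: int = 1014,
    igr_len: int = 300,
    orf2_len: int = 3825,
    utr3_len: int = 150,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """A synthetic L1-like element: GC-rich promoter, two stop-free ORFs, an
    intergenic spacer and a short 3'UTR carrying a polypurine tract."""
    utr5 = promoter if promoter is not None else _random_dna(rng, utr5_len, 0.60)
    orf1 = _random_orf(rng, orf1_len // 3)
    igr = _random_dna(rng, igr_len, 0.40)
    orf2 = _random_orf(rng, orf2_len // 3)
    utr3 = _random_dna(rng, utr3_len - 10, 0.35) + "AGGAAGAGGA"
    seq = utr5 + orf1 + igr + orf2 + utr3
    spans, pos = {}, 0
    for name, part in zip(FEATURES, (utr5, orf1, igr, orf2, utr3)):
        spans[name] = (pos, pos + len(part))
        pos += len(part)
    return seq, spans


def _repair_stops(
    seq: str, spans: dict[str, tuple[int, int]], rng: np.random.Generator
) -> str:
    """Replace in-frame stop codons inside ORF1/ORF2 with sense codons.

    Family progenitors are active elements, so their reading frames are kept
    open even though the rest of the sequence diverges neutrally."""
    out = list(seq)
    for orf in ("ORF1", "ORF2"):
        s, e = spans[orf]
        for i in range(s, e - 2, 3):
            if seq[i : i + 3] in ("TAA", "TAG", "TGA"):
                out[i : i + 3] = rng.choice(_SENSE_CODONS)
    return "".join(out)


def rt_protein_query(source: str, spans: dict[str, tuple[int, int]]) -> str:
    """Protein sequence of the RT domain of ORF2, the harvest anchor."""
    s, _ = spans["ORF2"]
    dna = source[s + RT_OFFSET : s + RT_OFFSET + RT_LENGTH]
    return str(Seq(dna).translate())


def motif_library(source: str, spans: dict[str, tuple[int, int]]) -> dict[str, str]:
    """ORF1/ORF2/3'UTR exemplars used to annotate harvested fragments."""
    return {
        name: source[spans[name][0] : spans[name][1]] for name in ("ORF1", "ORF2", "3UTR")
    }


@dataclass
class ScenarioBundle:
    """A scenario together with the search inputs derived from its ancestor."""

    scenario: AmplificationScenario
    rt_query: str
    motif_library: dict[str, str]
    ancestor: str
    ancestor_spans: dict[str, tuple[int, int]]
    promoters: dict[int, str] = field(default_factory=dict)


def demo_scenario(
    seed: int = 0,
    n_families: int = 3,
    n_inserts: int = 120,
    p_full_length: float = DEFAULT_P_FULL_LENGTH,
    between_divergence: float = 0.08,
    window_myr: float = 4.0,
    age_step_myr: float = 6.0,
    rate: float = DEFAULT_RATE,
    cpg_multiplier: float = 1.0,
    promoter_types: list[int] | None = None,
    genome_slack: int | None = None,
) -> ScenarioBundle:
    """Build a multi-family amplification scenario from a common ancestor.

    Families descend from one ancestral element (pairwise source divergence
    ~`between_divergence`), carry promoters of the given types (families of
    the same type share a promoter; different types are non-homologous), and
    amplify in staggered windows of `window_myr` Myr, the youngest starting
    at present, echoing the staircase of family ages seen in real genomes.
    """
    rng = np.random.default_rng(seed)
    ancestor, spans = synthetic_l1_source(rng)
    if promoter_types is None:
        # youngest family gets its own recruited promoter; older ones share
        promoter_types = [1] + [2] * (n_families - 1) if n_families > 1 else [1]
    proms = {
        pt: _random_dna(rng, 2000, 0.60) for pt in sorted(set(promoter_types))
    }
    u5s, u5e = spans["5UTR"]
    families = []
    for i in range(n_families):
        body = evolve_sequence(
            ancestor[u5e:], t=(between_divergence / 2) / rate, rate=rate, rng=rng
        )
        prom = evolve_sequence(proms[promoter_types[i]], t=0.01 / rate, rate=rate, rng=rng)
        source = prom + body
        fspans = {"5UTR": (0, len(prom))}
        shift = len(prom) - (u5e - u5s)
        for name in FEATURES[1:]:
            s, e = spans[name]
            fspans[name] = (s + shift, e + shift)
        source = _repair_stops(source, fspans, rng)
        t_end = i * age_step_myr
        families.append(
            FamilySpec(
                name=f"fam{i + 1}",
                source_sequence=source,
                feature_spans=fspans,
                promoter_type=promoter_types[i],
                t_start=t_end + window_myr,
                t_end=t_end,
                n_inserts=n_inserts,
                p_full_length=p_full_length,
            )
        )
    total = sum(f.length * f.n_inserts for f in families)
    if genome_slack is None:
        genome_slack = 2 * total  # elements end up ~1/3 of the genome
    scenario = AmplificationScenario(
        families=families,
        genome_length=total + genome_slack,
        rate_per_lineage=rate,
        cpg_multiplier=cpg_multiplier,
        seed=int(np.random.default_rng(seed + 1).integers(0, 2**31 - 1)),
    )
    return ScenarioBundle(
        scenario=scenario,
        rt_query=rt_protein_query(ancestor, spans),
        motif_library=motif_library(ancestor, spans),
        ancestor=ancestor,
        ancestor_spans=spans,
        promoters=proms,
    )


def synthesize_fl_elements(
    scenario: AmplificationScenario, seed: int | None = None
) -> tuple[list, dict[str, str]]:
    """Draw the scenario's copies as full-length elements without genome
    placement (classification-stage input with known labels).

    Returns (elements, truth labels element_id -> family name). Elements are
    `harvest.FullLengthElement` records whose feature spans are the family
    source spans.
    """
    from .harvest import FullLengthElement  # deferred: harvest must not import us

    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    elements, labels = [], {}
    for spec in scenario.families:
        times = rng.uniform(spec.t_end, spec.t_start, size=spec.n_inserts)
        for i in range(spec.n_inserts):
            seq = evolve_sequence(
                spec.source_sequence,
                float(times[i]),
                scenario.rate_per_lineage,
                scenario.cpg_multiplier,
                rng=rng,
            )
            eid = f"{spec.name}_{i:04d}"
            elements.append(
                FullLengthElement(
                    element_id=eid,
                    contig="synthetic",
                    start=0,
                    end=len(seq),
                    strand="+",
                    feature_spans=dict(spec.feature_spans),
                    upstream_context="",
                    sequence=seq,
                )
            )
            labels[eid] = spec.name
    return elements, labels


def simulate_orthologous_loci(
    n_loci: int,
    rate_a: float,
    rate_b: float,
    t_start: float,
    t_end: float,
    locus_length: int = 600,
    seed: int = 0,
) -> tuple[str, list[tuple[str, str]]]:
    """Orthologous-insert panels for between-lineage rate comparison.

    Each locus is one ancestral insertion carried by both descendant genomes;
    its copy in genome A evolves for its age at `rate_a`, the orthologous
    copy in genome B at `rate_b`. Returns (consensus, [(seq_a, seq_b), ...]).
    """
    rng = np.random.default_rng(seed)
    consensus = _random_dna(rng, locus_length, 0.42)
    times = rng.uniform(t_end, t_start, size=n_loci)
    pairs = []
    for t in times:
        a = evolve_sequence(consensus, float(t), rate_a, rng=rng)
        b = evolve_sequence(consensus, float(t), rate_b, rng=rng)
        pairs.append((a, b))
    return consensus, pairs


@dataclass
class RecombinationPanel:
    """Synthetic stand-in for a set of family ORF2 consensus sequences with a
    single known recombination event (the real consensuses are supplementary
    data of the original study and are not redistributed here)."""

    sequences: dict[str, str]
    recombinant: str
    parent_5p: str  # lineage donating columns [1, breakpoint]
    parent_3p: str  # lineage donating columns (breakpoint, L]
    breakpoint: int  # 1-based alignment column of the last 5'-donor site


def synthetic_orf2_consensus_panel(
    seed: int = 0,
    length: int = 3825,
    breakpoint: int = 2207,
    rate: float = DEFAULT_RATE,
) -> RecombinationPanel:
    """Build a synthetic ORF2 consensus panel mirroring the two-lineage
    structure in which recombination was observed: an Ec1-like clade, an
    Ec2-like clade, an outgroup, and a chimera ("L1_Ec1_X") whose 5' portion
    up to `breakpoint` derives from the Ec2 lineage (sister to "L1_Ec2_VII")
    and whose 3' portion is an ordinary Ec1 member.

    The columns immediately flanking the breakpoint are made informative
    (5'-side: chimera agrees with its Ec2 parent while the Ec1 clade differs;
    3'-side: chimera disagrees with the Ec2 parent) so that breakpoint
    localization is exact rather than limited by the local density of
    substitutions.
    """
    rng = np.random.default_rng(seed)
    anc = _random_orf(rng, length // 3)
    L = len(anc)

    def ev(seq: str, d: float) -> str:
        return evolve_sequence(seq, t=(d / 2) / rate, rate=rate, rng=rng)

    anc_ec1 = ev(anc, 0.05)
    anc_ec2 = ev(anc, 0.05)
    seqs = {
        "L1_Perissodactyla7_I": ev(anc, 0.09),
        "L1_Ec1_IX": ev(anc_ec1, 0.02),
        "L1_Ec1_VI": ev(anc_ec1, 0.02),
        "L1_Ec2_VI": ev(anc_ec2, 0.02),
        "L1_Ec2_V": ev(anc_ec2, 0.02),
        "L1_Ec2_VII": ev(anc_ec2, 0.02),
    }
    donor_5p = ev(seqs["L1_Ec2_VII"], 0.015)  # close to Ec2_VII on the 5' side
    tail_3p = ev(anc_ec1, 0.02)  # ordinary Ec1 member on the 3' side
    chimera = list(donor_5p[:breakpoint] + tail_3p[breakpoint:])

    # make the breakpoint-flanking columns informative (fixture contract)
    others = {"A": "C", "C": "G", "G": "T", "T": "A"}
    i = breakpoint - 1  # 0-based column of the last 5'-donor site
    base = seqs["L1_Ec2_VII"][i]
    chimera[i] = base  # chimera matches its 5' parent...
    for nm in ("L1_Ec1_IX", "L1_Ec1_VI", "L1_Perissodactyla7_I"):
        s = list(seqs[nm])
        s[i] = others[base]  # ...while the other lineage differs
        seqs[nm] = "".join(s)
    for j in range(breakpoint, min(breakpoint + 4, L)):  # dense 3'-side signal
        chimera[j] = others[seqs["L1_Ec2_VII"][j]]
        s = list(seqs["L1_Ec1_IX"])
        s[j] = chimera[j]
        seqs["L1_Ec1_IX"] = "".join(s)
    seqs["L1_Ec1_X"] = "".join(chimera)
    order = [
        "L1_Ec1_X",
        "L1_Ec1_IX",
        "L1_Ec1_VI",
        "L1_Ec2_VII",
        "L1_Ec2_VI",
        "L1_Ec2_V",
        "L1_Perissodactyla7_I",
    ]
    return RecombinationPanel(
        sequences={nm: seqs[nm] for nm in order},
        recombinant="L1_Ec1_X",
        parent_5p="L1_Ec2_VII",
        parent_3p="L1_Ec1_IX",
        breakpoint=breakpoint,
    )
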