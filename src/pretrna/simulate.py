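"""Seeded generators for synthetic tRNA gene loci and tRNA-seq read sets.

The genome generator emulates the architecture the analysis stages measure:
loci with a configurable 3'-trailer length distribution in front of a poly-T
Pol III terminator, leader composition with an N-1|N73 pairing-avoidance
knob, a discriminator base distribution, and optional introns — with every
drawn quantity exported as ground truth.  The read generator emits mixtures
of CCA-ended mature reads and U1..U10-tailed precursor reads per
isoacceptor, with an IP enrichment factor applied to the precursor class,
so the fishing/binning/enrichment stages can be validated end to end.

Both generators are pure functions of (inputs, configuration, seed): two
runs with the same seed produce byte-identical output files.

By construction the synthetic trailer contains no T at all, so the placed
terminator is always the first T-run at any minimum-run setting and the
ground-truth trailer length is exact rather than distributional.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (GeneAnnotation, GenomeSource, TRNAGene,
                      reverse_complement)

BASES = ("A", "C", "G", "T")
WC = {"A": "T", "T": "A", "C": "G", "G": "C"}

# standard genetic code, anticodon -> amino-acid 3-letter-ish isotype code
_CODON_TABLE = {
    "TTT": "Phe", "TTC": "Phe", "TTA": "Leu", "TTG": "Leu", "CTT": "Leu",
    "CTC": "Leu", "CTA": "Leu", "CTG": "Leu", "ATT": "Ile", "ATC": "Ile",
    "ATA": "Ile", "ATG": "Met", "GTT": "Val", "GTC": "Val", "GTA": "Val",
    "GTG": "Val", "TCT": "Ser", "TCC": "Ser", "TCA": "Ser", "TCG": "Ser",
    "CCT": "Pro", "CCC": "Pro", "CCA": "Pro", "CCG": "Pro", "ACT": "Thr",
    "ACC": "Thr", "ACA": "Thr", "ACG": "Thr", "GCT": "Ala", "GCC": "Ala",
    "GCA": "Ala", "GCG": "Ala", "TAT": "Tyr", "TAC": "Tyr", "CAT": "His",
    "CAC": "His", "CAA": "Gln", "CAG": "Gln", "AAT": "Asn", "AAC": "Asn",
    "AAA": "Lys", "AAG": "Lys", "GAT": "Asp", "GAC": "Asp", "GAA": "Glu",
    "GAG": "Glu", "TGT": "Cys", "TGC": "Cys", "TGG": "Trp", "CGT": "Arg",
    "CGC": "Arg", "CGA": "Arg", "CGG": "Arg", "AGT": "Ser", "AGC": "Ser",
    "AGA": "Arg", "AGG": "Arg", "GGT": "Gly", "GGC": "Gly", "GGA": "Gly",
    "GGG": "Gly",
}
#: sense codons, as (isotype, anticodon) pairs in a fixed order
SENSE_ANTICODONS: list[tuple[str, str]] = [
    (aa, reverse_complement(codon)) for codon, aa in _CODON_TABLE.items()
]


@dataclass
class SpeciesProfile:
    """Generative parameters for one synthetic species.

    Distributions are dicts with a ``family`` key: ``point`` (value),
    ``geometric`` (p; support 0,1,2,.. with mean (1-p)/p), ``histogram``
    (probs: {value: weight}), or ``normal`` (mean, sd; rounded to int).
    ``pairing_avoidance`` is the probability mass removed from the
    Watson-Crick complement of N73 when drawing N-1 (1.0 means the
    complement is never drawn).
    """

    name: str = "synthetic"
    n_genes: int = 200
    trailer_distribution: dict = field(
        default_factory=lambda: {"family": "geometric", "p": 0.4})
    terminator_run_length: int = 4
    leader_marginal: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
    n1_marginal: dict[str, float] | None = None
    pairing_avoidance: float = 0.0
    discriminator_distribution: dict[str, float] = field(
        default_factory=lambda: {"A": 0.50, "C": 0.125, "G": 0.25, "T": 0.125})
    mature_length_distribution: dict = field(
        default_factory=lambda: {"family": "normal", "mean": 74.0, "sd": 3.4})
    intron_probability: float = 0.1
    intron_length_range: tuple[int, int] = (8, 30)
    copy_number_distribution: dict = field(
        default_factory=lambda: {"family": "point", "value": 1})
    leader_length: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pairing_avoidance <= 1.0:
            raise ValueError("pairing_avoidance must be in [0, 1]")
        if self.terminator_run_length < 4:
            raise ValueError("terminator_run_length must be >= 4")
        for dist in (self.leader_marginal, self.discriminator_distribution):
            total = sum(dist.get(b, 0.0) for b in BASES)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"base distribution does not sum to 1: {dist}")


@dataclass
class ReadSimConfig:
    """Generative parameters for synthetic input/IP read sets.

    ``tail_length_distributions`` maps a condition label to a distribution
    over uridylate tail lengths 1..10; conditions without an entry fall back
    to "WT".  ``ip_enrichment_factor`` f is the factor by which the
    precursor (uridylate-tailed) class's share of the library is amplified
    in IP replicates relative to input; mature reads are the background
    that fills the remaining library fraction.  Under per-replicate CPM
    normalisation this makes the expected premature IP/input CPM ratio
    exactly f for every isoacceptor (and depletes mature reads
    correspondingly, as seen in real IP libraries).  Requires
    f * (1 - mature_fraction) < 1.  The default ``mature_fraction`` of 0.8
    emulates a size-selected library that retains a substantial nascent
    pre-tRNA population alongside the dominant mature class.
    """

    depth: int = 100_000
    read_length: int = 75
    mature_fraction: float = 0.8
    ip_enrichment_factor: float = 3.0
    tail_length_distributions: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "WT": {1: 0.35, 2: 0.30, 3: 0.18, 4: 0.09, 5: 0.05, 6: 0.03},
            "KO": {1: 0.10, 2: 0.15, 3: 0.20, 4: 0.20, 5: 0.15, 6: 0.10,
                   7: 0.05, 8: 0.05},
        })
    expression_sigma: float = 0.2   # lognormal spread of per-locus expression
    expression_weights: dict[str, float] | None = None  # per-locus; None = drawn
    error_rate: float = 0.0         # per-base substitution rate (off by default)
    bait_length: int = 36
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mature_fraction <= 1.0:
            raise ValueError("mature_fraction must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for dist in self.tail_length_distributions.values():
            if any(not 1 <= n <= 10 for n in dist):
                raise ValueError("tail lengths must lie in 1..10")
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError("tail length distribution does not sum to 1")


def _draw_length(dist: Mapping, rng: np.random.Generator) -> int:
    family = dist["family"]
    if family == "point":
        return int(dist["value"])
    if family == "geometric":
        return int(rng.geometric(dist["p"]) - 1)
    if family == "histogram":
        values = sorted(dist["probs"])
        probs = np.array([dist["probs"][v] for v in values], dtype=float)
        return int(rng.choice(values, p=probs / probs.sum()))
    if family == "normal":
        return int(round(rng.normal(dist["mean"], dist["sd"])))
    raise ValueError(f"unknown distribution family {family!r}")


def _draw_base(dist: Mapping[str, float], rng: np.random.Generator) -> str:
    probs = np.array([dist.get(b, 0.0) for b in BASES], dtype=float)
    return BASES[int(rng.choice(4, p=probs / probs.sum()))]


def n1_conditional(profile: SpeciesProfile, discriminator: str) -> dict[str, float]:
    """The generating N-1 distribution given a discriminator base.

    Starts from the N-1 marginal (defaulting to the leader marginal) and
    removes a ``pairing_avoidance`` fraction of the Watson-Crick complement's
    mass, renormalising over the remaining bases.
    """
    marginal = profile.n1_marginal or profile.leader_marginal
    weights = {b: marginal.get(b, 0.0) for b in BASES}
    weights[WC[discriminator]] *= (1.0 - profile.pairing_avoidance)
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("N-1 conditional distribution has no mass left")
    return {b: w / total for b, w in weights.items()}


def _random_seq(rng: np.random.Generator, length: int,
                alphabet: Sequence[str] = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


@dataclass
class SimulatedGenome:
    """Everything one synthetic species run produces, in memory."""

    genome: GenomeSource
    annotations: list[GeneAnnotation]
    truth: pd.DataFrame


def simulate_genome(profile: SpeciesProfile,
                    seed: int | None = None) -> SimulatedGenome:
    """Build a genome, BED12-ready annotations, and a ground-truth table.

    Loci are placed on alternating random strands along one contig.  Within
    an isoacceptor (copy number > 1) all loci share the mature sequence;
    leaders and trailers are drawn independently per locus.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    anticodons = list(SENSE_ANTICODONS)
    rng.shuffle(anticodons)

    # assign loci to isoacceptors according to the copy-number distribution
    groups: list[tuple[str, str, int]] = []   # (isotype, anticodon, n_copies)
    remaining = profile.n_genes
    while remaining > 0:
        if anticodons:
            isotype, anticodon = anticodons.pop()
        else:  # more isoacceptor groups than sense anticodons: reuse randomly
            isotype, anticodon = SENSE_ANTICODONS[int(rng.integers(0, 61))]
        copies = min(remaining, max(1, _draw_length(
            profile.copy_number_distribution, rng)))
        groups.append((isotype, anticodon, copies))
        remaining -= copies

    chunks: list[str] = []
    pos = 0
    annotations: list[GeneAnnotation] = []
    truth_rows: list[dict] = []
    seen_suffixes: set[str] = set()
    gene_no = 0
    for isotype, anticodon, copies in groups:
        mlen = max(62, _draw_length(profile.mature_length_distribution, rng))
        while True:
            mature = (_random_seq(rng, mlen - 1)
                      + _draw_base(profile.discriminator_distribution, rng))
            if mature[-profile.leader_length:] not in seen_suffixes:
                seen_suffixes.add(mature[-profile.leader_length:])
                break
        discriminator = mature[-1]
        cond = n1_conditional(profile, discriminator)
        for _ in range(copies):
            gene_no += 1
            gene_id = f"{profile.name}-tRNA-{isotype}-{anticodon}-{gene_no}"
            leader = (_random_seq_from(rng, profile.leader_length - 1,
                                       profile.leader_marginal)
                      + _draw_base(cond, rng))
            trailer_len = _draw_length(profile.trailer_distribution, rng)
            trailer = _random_seq(rng, trailer_len, alphabet=("A", "C", "G"))
            terminator = "T" * profile.terminator_run_length
            cap = _random_seq(rng, 6, alphabet=("A", "C", "G"))

            intron = ""
            cut = 0
            if rng.random() < profile.intron_probability:
                ilen = int(rng.integers(profile.intron_length_range[0],
                                        profile.intron_length_range[1] + 1))
                intron = _random_seq(rng, ilen)
                cut = int(rng.integers(30, min(41, mlen - 5)))
            body = mature[:cut] + intron + mature[cut:] if intron else mature

            block = leader + body + trailer + terminator + cap
            spacer = _random_seq(rng, int(rng.integers(30, 81)))
            strand = "+" if rng.random() < 0.5 else "-"
            placed = block if strand == "+" else reverse_complement(block)
            insert_at = pos + len(spacer)
            chunks.append(spacer + placed)
            pos = insert_at + len(placed)

            lead = profile.leader_length
            if strand == "+":
                start = insert_at + lead
                end = start + len(body)
                introns = ([(start + cut, start + cut + len(intron))]
                           if intron else [])
            else:
                start = insert_at + len(block) - lead - len(body)
                end = insert_at + len(block) - lead
                introns = ([(insert_at + len(block) - lead - cut - len(intron),
                             insert_at + len(block) - lead - cut)]
                           if intron else [])
            annotations.append(GeneAnnotation(
                gene_id=gene_id, species=profile.name, isotype=isotype,
                anticodon=anticodon, contig=f"{profile.name}_chr1",
                start=start, end=end, strand=strand, intron_blocks=introns))
            truth_rows.append({
                "gene_id": gene_id, "isotype": isotype, "anticodon": anticodon,
                "isoacceptor": f"{isotype}-{anticodon}", "strand": strand,
                "trailer_length": trailer_len, "mature_length": mlen,
                "discriminator": discriminator, "n_minus_1": leader[-1],
                "intron_length": len(intron), "copies_in_isoacceptor": copies,
            })
    genome = GenomeSource({f"{profile.name}_chr1": "".join(chunks)})
    return SimulatedGenome(genome=genome, annotations=annotations,
                           truth=pd.DataFrame(truth_rows))


def _random_seq_from(rng: np.random.Generator, length: int,
                     dist: Mapping[str, float]) -> str:
    probs = np.array([dist.get(b, 0.0) for b in BASES], dtype=float)
    probs = probs / probs.sum()
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=probs))


def write_genome_fasta(sim: SimulatedGenome, path: str | Path,
                       width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in sim.genome.contigs.items():
            fh.write(f">{cid}\n")
            for off in range(0, len(seq), width):
                fh.write(seq[off:off + width] + "\n")


def write_annotations_bed12(sim: SimulatedGenome, path: str | Path) -> None:
    """Write BED12 with intron-aware blocks (gaps between blocks = introns)."""
    with open(path, "w") as fh:
        for ann in sim.annotations:
            boundaries = [ann.start]
            for (s, e) in sorted(ann.intron_blocks):
                boundaries += [s, e]
            boundaries.append(ann.end)
            starts = boundaries[0::2]
            ends = boundaries[1::2]
            sizes = ",".join(str(e - s) for s, e in zip(starts, ends))
            offsets = ",".join(str(s - ann.start) for s in starts)
            fh.write("\t".join(map(str, [
                ann.contig, ann.start, ann.end, ann.gene_id, 0, ann.strand,
                ann.start, ann.end, "0,0,0", len(starts), sizes, offsets,
            ])) + "\n")


def assign_expression(catalog: Sequence[TRNAGene],
                      config: ReadSimConfig) -> dict[str, float]:
    """Per-locus expression weights: fixed for a (catalog, config) pair.

    IP and input replicates of the same sample must share these weights, so
    they are drawn from a generator seeded by the config seed alone, never
    by the per-replicate seed.  Explicit ``config.expression_weights`` win.
    """
    if config.expression_weights is not None:
        return dict(config.expression_weights)
    rng = np.random.default_rng(0 if config.seed is None else config.seed)
    return {g.gene_id: float(rng.lognormal(0.0, config.expression_sigma))
            for g in sorted(catalog, key=lambda g: g.gene_id)}


def _isoacceptor_cells(catalog: Sequence[TRNAGene], config: ReadSimConfig,
                       condition: str,
                       ) -> tuple[list[tuple[str, str, int]], np.ndarray, pd.DataFrame]:
    """Sampling cells (isoacceptor, kind, tail_len) and their probabilities."""
    by_iso: dict[str, list[TRNAGene]] = {}
    for g in catalog:
        by_iso.setdefault(g.isoacceptor, []).append(g)
    tail_dist = config.tail_length_distributions.get(
        condition, config.tail_length_distributions["WT"])
    iso_ids = sorted(by_iso)
    # isoacceptor weight = sum of its locus weights (copy number scales it)
    locus_w = assign_expression(catalog, config)
    weights = {iso: sum(locus_w[g.gene_id] for g in by_iso[iso])
               for iso in iso_ids}
    m = config.mature_fraction
    cells: list[tuple[str, str, int]] = []
    w: list[float] = []
    for iso in iso_ids:
        cells.append((iso, "mature", 0))
        w.append(weights[iso] * m)
        for n, p in sorted(tail_dist.items()):
            cells.append((iso, "premature", n))
            w.append(weights[iso] * (1.0 - m) * p)
    probs = np.array(w, dtype=float)
    probs /= probs.sum()
    if condition == "IP":
        # amplify the premature class's library share by f; mature reads fill
        # the remaining fraction, keeping per-isoacceptor fold uniform at f
        f = config.ip_enrichment_factor
        premature = np.array([c[1] == "premature" for c in cells])
        s = probs[premature].sum()
        if f * s >= 1.0:
            raise ValueError(
                "ip_enrichment_factor times premature fraction must be < 1")
        probs[premature] *= f
        probs[~premature] *= (1.0 - f * s) / (1.0 - s)
    truth = pd.DataFrame({
        "isoacceptor": [c[0] for c in cells],
        "kind": [c[1] for c in cells],
        "tail_length": [c[2] for c in cells],
        "probability": probs,
        "n_loci": [len(by_iso[c[0]]) for c in cells],
    })
    return cells, probs, truth


@dataclass
class SimulatedReads:
    replicate: str
    condition: str
    sequences: list[str]
    truth: pd.DataFrame  # per-cell sampling probabilities and drawn counts


def simulate_reads(catalog: Sequence[TRNAGene], config: ReadSimConfig,
                   condition: str = "input", replicate: str = "rep1",
                   seed: int | None = None) -> SimulatedReads:
    """Draw one replicate of reads from the per-cell mixture.

    Every read is a 3'-anchored slice of its isoacceptor's mature sequence
    plus either ``CCA`` (mature) or a drawn uridylate tail (premature),
    padded on the 5' side to the configured read length.  IP replicates
    multiply every premature cell's weight by ``ip_enrichment_factor``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    max_add = 10
    min_mature = config.bait_length
    if config.read_length < min_mature + max_add:
        raise ValueError("read length shorter than bait plus maximum tail")
    cells, probs, truth = _isoacceptor_cells(catalog, config, condition)
    counts = rng.multinomial(config.depth, probs)
    truth = truth.assign(count=counts)
    rep_seq: dict[str, str] = {}
    for g in catalog:
        rep_seq.setdefault(g.isoacceptor, g.mature_sequence)
    sequences: list[str] = []
    for (iso, kind, tail_len), n in zip(cells, counts):
        if n == 0:
            continue
        addition = "CCA" if kind == "mature" else "T" * tail_len
        mature = rep_seq[iso]
        body_len = min(len(mature), config.read_length - len(addition))
        read = mature[-body_len:] + addition
        sequences.extend([read] * int(n))
    if config.error_rate > 0:
        sequences = [_mutate(s, config.error_rate, rng) for s in sequences]
    # deterministic shuffle so replicate files are not block-sorted by cell
    order = rng.permutation(len(sequences))
    sequences = [sequences[i] for i in order]
    return SimulatedReads(replicate=replicate, condition=condition,
                          sequences=sequences, truth=truth)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[int(rng.integers(0, 4))]
    return "".join(out)


def write_fastq(sim: SimulatedReads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sim.sequences):
            fh.write(f"@sim_{sim.condition}_{sim.replicate}_{i}\n{seq}\n+\n"
                     + "I" * len(seq) + "\n")


def profile_from_dict(d: Mapping) -> SpeciesProfile:
    d = dict(d)
    if "intron_length_range" in d:
        d["intron_length_range"] = tuple(d["intron_length_range"])
    return SpeciesProfile(**d)


def read_config_from_dict(d: Mapping) -> ReadSimConfig:
    d = dict(d)
    if "tail_length_distributions" in d:
        d["tail_length_distributions"] = {
            cond: {int(k): float(v) for k, v in dist.items()}
            for cond, dist in d["tail_length_distributions"].items()}
    return ReadSimConfig(**d)


def profile_to_dict(profile: SpeciesProfile) -> dict:
    d = dataclasses.asdict(profile)
    d["intron_length_range"] = list(d["intron_length_range"])
    return d
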