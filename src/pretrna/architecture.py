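"""Pre-tRNA architecture statistics: terminator scanning, trailer/mature length
distributions, leader base composition, and leader/trailer pairing avoidance.

The 3'-trailer of a pre-tRNA is the stretch between the discriminator base
(N73, last mature nucleotide) and the RNA Pol III terminator, detected here
as the first run of at least ``k`` consecutive T on the coding strand of the
downstream flank.  Trailer length is therefore the offset of that run;
a run starting immediately after N73 gives a zero-length trailer.  Leader
composition is summarised as a position-frequency matrix over N-W..N-1,
optionally conditioned on the discriminator base, which quantifies how
strongly the last leader base avoids Watson-Crick pairing with N73.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import TRNAGene
from .stats import AnovaResult, one_way_anova, tukey_posthoc  # noqa: F401 (re-export)

BASES = ("A", "C", "G", "T")
WC_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class TrailerCall:
    """Terminator-scan result for one gene at one minimum-run setting ``k``."""

    gene_id: str
    k: int
    terminator_found: bool
    trailer_length: int | None = None
    excluded: bool = False
    flags: tuple[str, ...] = ()


@dataclass
class ArchitectureStats:
    species: str
    n_genes_total: int
    n_trailer_analyzed: int
    trailer_mean: float
    trailer_sd: float
    trailer_mode: int
    trailer_histogram: dict[int, int]
    mature_mean: float
    mature_sd: float
    flags: tuple[str, ...] = ()


@dataclass
class LeaderMatrix:
    """Base x position counts/frequencies over leader positions N-W .. N-1."""

    window: int
    counts: pd.DataFrame          # index BASES, columns "N-W".."N-1"
    frequencies: pd.DataFrame
    n_sequences: int
    condition: str | None = None  # discriminator base, if conditioned


@dataclass
class PairingTable:
    """Per-discriminator-base N-1 composition and Watson-Crick pairing rate."""

    rows: pd.DataFrame  # columns: discriminator, n_genes, freq_A..freq_T,
                        #          wc_complement_frequency, expected_wc_frequency


def scan_terminator(downstream_flank: str, min_run: int = 4) -> TrailerCall:
    """Locate the first >=``min_run`` T run in a transcript-oriented flank.

    Returns the trailer length (offset of the run start; 0 when termination
    begins immediately after the discriminator).  A run may be longer than
    ``min_run`` and may not span an N.  ``gene_id`` is left blank; callers
    scanning catalogs fill it in.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    flank = downstream_flank.upper()
    if not flank:
        return TrailerCall("", min_run, False, flags=("short_flank",))
    run = 0
    for i, base in enumerate(flank):
        run = run + 1 if base == "T" else 0
        if run == min_run:
            return TrailerCall("", min_run, True, trailer_length=i - min_run + 1)
    return TrailerCall("", min_run, False)


def scan_catalog(genes: Iterable[TRNAGene], min_run: int = 4,
                 max_trailer: int = 20) -> list[TrailerCall]:
    """Terminator-scan every gene; trailers longer than ``max_trailer`` are
    flagged excluded (they still count as found)."""
    calls = []
    for g in genes:
        call = scan_terminator(g.downstream_flank, min_run)
        call.gene_id = g.gene_id
        if call.terminator_found and call.trailer_length > max_trailer:
            call.excluded = True
        calls.append(call)
    return calls


def mature_length(gene: TRNAGene) -> int:
    """Length of the spliced mature body (+1 through N73, introns excluded)."""
    return len(gene.mature_sequence)


def summarize_species(calls: Sequence[TrailerCall], genes: Sequence[TRNAGene],
                      species: str | None = None) -> ArchitectureStats:
    """Per-species trailer and mature-length summary.

    Mean/SD (sample SD, n-1) are over terminator-found, non-excluded calls;
    the modal trailer length breaks ties toward the smaller length.
    """
    lengths = sorted(
        c.trailer_length for c in calls if c.terminator_found and not c.excluded
    )
    flags: list[str] = []
    if species is None:
        species = genes[0].species if genes else ""
    if not lengths:
        flags.append("no_analyzable_trailers")
        trailer_mean = trailer_sd = float("nan")
        mode = -1
        hist: dict[int, int] = {}
    else:
        arr = np.asarray(lengths, dtype=float)
        trailer_mean = float(arr.mean())
        trailer_sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        vals, counts = np.unique(arr.astype(int), return_counts=True)
        mode = int(vals[np.argmax(counts)])  # unique() sorts: ties -> smallest
        hist = dict(zip((int(v) for v in vals), (int(c) for c in counts)))
    mlens = np.asarray([mature_length(g) for g in genes], dtype=float)
    return ArchitectureStats(
        species=species,
        n_genes_total=len(genes),
        n_trailer_analyzed=len(lengths),
        trailer_mean=trailer_mean,
        trailer_sd=trailer_sd,
        trailer_mode=mode,
        trailer_histogram=hist,
        mature_mean=float(mlens.mean()) if mlens.size else float("nan"),
        mature_sd=float(mlens.std(ddof=1)) if mlens.size > 1 else 0.0,
        flags=tuple(flags),
    )


def compare_species_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA across species (trailer or mature lengths)."""
    return one_way_anova(groups)


def leader_logo(genes: Iterable[TRNAGene], window: int = 10,
                condition: str | None = None) -> LeaderMatrix:
    """Position-frequency matrix of leader bases over N-window .. N-1.

    Genes with an upstream flank shorter than the window are dropped; with
    ``condition`` set, only genes with that discriminator base contribute.
    """
    cols = [f"N-{i}" for i in range(window, 0, -1)]
    counts = pd.DataFrame(0, index=list(BASES), columns=cols, dtype=int)
    n = 0
    for g in genes:
        if condition is not None and g.discriminator != condition:
            continue
        if len(g.upstream_flank) < window:
            continue
        tail = g.upstream_flank[-window:]
        for col, base in zip(cols, tail):
            if base in BASES:
                counts.loc[base, col] += 1
        n += 1
    totals = counts.sum(axis=0)
    freqs = counts / totals.replace(0, np.nan)
    return LeaderMatrix(window=window, counts=counts,
                        frequencies=freqs.fillna(0.0), n_sequences=n,
                        condition=condition)


def discriminator_composition(genes: Sequence[TRNAGene]) -> dict[str, float]:
    """Base frequencies of the discriminator N73 over {A,C,G,T}."""
    if not genes:
        raise ValueError("empty gene list")
    counts = {b: 0 for b in BASES}
    total = 0
    for g in genes:
        if g.discriminator in counts:
            counts[g.discriminator] += 1
            total += 1
    if total == 0:
        raise ValueError("no genes with an unambiguous discriminator")
    return {b: counts[b] / total for b in BASES}


def pairing_avoidance(genes: Sequence[TRNAGene]) -> PairingTable:
    """Quantify N-1 vs N73 Watson-Crick pairing.

    For each discriminator base b the table reports the N-1 base composition
    of genes with that discriminator, the observed fraction whose N-1 is the
    WC complement of b, and the fraction expected under independence (the
    marginal N-1 frequency of complement(b)).  Discriminator classes with no
    genes are omitted.
    """
    usable = [g for g in genes
              if g.n_minus_1 in BASES and g.discriminator in BASES]
    if not usable:
        raise ValueError("no genes with defined N-1 and discriminator")
    marginal = {b: sum(1 for g in usable if g.n_minus_1 == b) / len(usable)
                for b in BASES}
    rows = []
    for b in BASES:
        sub = [g for g in usable if g.discriminator == b]
        if not sub:
            continue
        comp = WC_COMPLEMENT[b]
        row = {"discriminator": b, "n_genes": len(sub)}
        for nb in BASES:
            row[f"freq_{nb}"] = sum(1 for g in sub if g.n_minus_1 == nb) / len(sub)
        row["wc_complement_frequency"] = row[f"freq_{comp}"]
        row["expected_wc_frequency"] = marginal[comp]
        rows.append(row)
    return PairingTable(rows=pd.DataFrame(rows))


def trailer_table(calls: Sequence[TrailerCall]) -> pd.DataFrame:
    """Per-gene trailer TSV payload."""
    return pd.DataFrame([
        {"gene_id": c.gene_id, "k": c.k, "terminator_found": c.terminator_found,
         "trailer_length": c.trailer_length if c.terminator_found else "",
         "excluded": c.excluded, "flags": ",".join(c.flags)}
        for c in calls
    ])


def stats_table(stats: Sequence[ArchitectureStats]) -> pd.DataFrame:
    """Per-species summary table mirroring the standard report columns."""
    return pd.DataFrame([
        {"species": s.species, "n_genes_total": s.n_genes_total,
         "mature_mean": s.mature_mean, "mature_sd": s.mature_sd,
         "n_trailer_analyzed": s.n_trailer_analyzed,
         "trailer_mean": s.trailer_mean, "trailer_sd": s.trailer_sd,
         "trailer_mode": s.trailer_mode}
        for s in stats
    ])
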