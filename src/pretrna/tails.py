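"""tRNA-seq read "fishing" and 3'-end binning.

Raw (unmapped) small-RNA reads are assigned to tRNA isoacceptors by exact
substring match against a unique 3'-terminal bait sequence per isoacceptor,
then binned by what follows the bait in the read: ``CCA`` marks a fully
3'-processed mature tRNA, a run of 1-10 T (uridylates in DNA space) marks a
nascent pre-tRNA trailer remnant, anything else is UNCLASSIFIED.  Counts are
normalised to counts per million fished reads (CPM) per replicate, and
IP/input CPM ratios give the per-isoacceptor fold enrichment, reported as
log2(fold + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .catalog import TRNAGene, _open_text
from .stats import bonferroni_by_level, pearson_log2, two_way_anova

log = logging.getLogger(__name__)

MAX_TAIL = 10
#: 3'-end bins, in reporting order
TAIL_BINS = ("CCA",) + tuple(f"U{i}" for i in range(1, MAX_TAIL + 1)) + ("UNCLASSIFIED",)
PREMATURE_BINS = tuple(f"U{i}" for i in range(1, MAX_TAIL + 1))


class BaitCollisionError(ValueError):
    """Two isoacceptors share a 3'-suffix at the chosen bait length."""


@dataclass
class BaitSet:
    """One unique 3'-terminal bait per isoacceptor."""

    baits: dict[str, str]                # isoacceptor id -> bait sequence
    discriminators: dict[str, str]       # isoacceptor id -> N73 base
    bait_length: int

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for iso, bait in self.baits.items():
            if bait in seen:
                raise BaitCollisionError(
                    f"bait shared by {seen[bait]} and {iso}; increase bait length")
            seen[bait] = iso


@dataclass
class BinCountTable:
    """Raw isoacceptor x 3'-end-bin counts for one replicate."""

    replicate: str
    counts: pd.DataFrame          # index isoacceptors, columns TAIL_BINS
    n_ambiguous: int = 0          # reads matching >= 2 baits (discarded)
    n_unmatched: int = 0          # reads matching no bait (ignored)

    @property
    def total_fished(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class CPMTable:
    """Counts-per-million version of a BinCountTable."""

    replicate: str
    cpm: pd.DataFrame
    total_fished: int
    per_bin: bool = False


def build_baits(catalog: Sequence[TRNAGene], bait_length: int = 36) -> BaitSet:
    """Derive one bait per isoacceptor from the catalog.

    Identical-sequence isodecoders collapse to a single entry first.  The
    bait is the ``bait_length``-nt 3' suffix of the spliced mature sequence
    (ending at the discriminator).  Isoacceptors whose distinct isodecoder
    sequences disagree at that suffix, or any two isoacceptors sharing a
    suffix, raise :class:`BaitCollisionError` naming the offenders.
    """
    by_iso: dict[str, set[str]] = {}
    for g in catalog:
        by_iso.setdefault(g.isoacceptor, set()).add(g.mature_sequence)
    shortest = min(len(s) for seqs in by_iso.values() for s in seqs)
    if bait_length > shortest:
        raise ValueError(
            f"bait length {bait_length} exceeds shortest mature sequence ({shortest})")
    baits: dict[str, str] = {}
    discs: dict[str, str] = {}
    for iso, seqs in sorted(by_iso.items()):
        suffixes = {s[-bait_length:] for s in seqs}
        if len(suffixes) > 1:
            raise BaitCollisionError(
                f"isoacceptor {iso} has {len(suffixes)} distinct {bait_length}-nt "
                "3'-suffixes across its isodecoders; fish them as separate entries")
        baits[iso] = suffixes.pop()
        discs[iso] = baits[iso][-1]
    return BaitSet(baits=baits, discriminators=discs, bait_length=bait_length)


def classify_tail(read_sequence: str, bait: str) -> str:
    """Bin a read by its 3' end relative to the rightmost bait occurrence.

    The bait ends at the discriminator base, so the suffix after it is the
    read's 3' addition: ``CCA`` -> mature; ``T``*n -> Un (n > 10 capped to
    U10); empty or anything else -> UNCLASSIFIED.
    """
    pos = read_sequence.rfind(bait)
    if pos < 0:
        raise ValueError("bait does not occur in read")
    suffix = read_sequence[pos + len(bait):]
    if suffix == "CCA":
        return "CCA"
    if suffix and set(suffix) == {"T"}:
        return f"U{min(len(suffix), MAX_TAIL)}"
    return "UNCLASSIFIED"


def fish_reads(reads: Iterable[str], baits: BaitSet,
               replicate: str = "rep1") -> BinCountTable:
    """Assign reads to isoacceptors by exact bait substring match and bin them.

    A read matching baits of two or more isoacceptors is discarded as
    ambiguous (counted); a read matching none is ignored (counted).
    """
    iso_ids = sorted(baits.baits)
    bait_items = [(iso, baits.baits[iso]) for iso in iso_ids]
    tally: dict[tuple[str, str], int] = {}
    n_ambiguous = n_unmatched = 0
    for seq in reads:
        hit: str | None = None
        hit_bait = ""
        ambiguous = False
        for iso, bait in bait_items:
            if bait in seq:
                if hit is not None:
                    ambiguous = True
                    break
                hit, hit_bait = iso, bait
        if ambiguous:
            n_ambiguous += 1
        elif hit is None:
            n_unmatched += 1
        else:
            key = (hit, classify_tail(seq, hit_bait))
            tally[key] = tally.get(key, 0) + 1
    counts = pd.DataFrame(0, index=iso_ids, columns=list(TAIL_BINS), dtype=int)
    for (iso, b), n in tally.items():
        counts.loc[iso, b] = n
    return BinCountTable(replicate=replicate, counts=counts,
                         n_ambiguous=n_ambiguous, n_unmatched=n_unmatched)


def read_fastq_sequences(path: str | Path) -> Iterable[str]:
    """Stream read sequences from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def fish_fastq(path: str | Path, baits: BaitSet, replicate: str) -> BinCountTable:
    return fish_reads(read_fastq_sequences(path), baits, replicate=replicate)


def cpm_normalize(table: BinCountTable, per_bin: bool = False) -> CPMTable:
    """Scale counts to counts per million fished reads.

    Default denominator is all fished reads in the replicate (classified +
    UNCLASSIFIED), so CPM sums to 1e6 per replicate.  ``per_bin=True``
    instead normalises each 3'-end bin column to 1e6 independently.
    """
    total = table.total_fished
    if total == 0:
        raise ValueError(f"replicate {table.replicate}: no fished reads")
    if per_bin:
        col_totals = table.counts.sum(axis=0)
        cpm = table.counts / col_totals.replace(0, np.nan) * 1e6
        cpm = cpm.fillna(0.0)
    else:
        cpm = table.counts / (total / 1e6)
    return CPMTable(replicate=table.replicate, cpm=cpm, total_fished=total,
                    per_bin=per_bin)


def average_cpm(tables: Sequence[CPMTable]) -> CPMTable:
    """Arithmetic mean of replicate CPM tables (e.g. averaged input)."""
    if not tables:
        raise ValueError("no CPM tables to average")
    mean = sum(t.cpm for t in tables) / len(tables)
    return CPMTable(replicate="+".join(t.replicate for t in tables), cpm=mean,
                    total_fished=sum(t.total_fished for t in tables),
                    per_bin=tables[0].per_bin)


def fold_enrichment(ip: CPMTable, input_: CPMTable,
                    pseudocount: float = 0.01) -> pd.DataFrame:
    """Per-isoacceptor IP/input enrichment, premature and mature separately.

    Premature CPM is the sum over U1..U10 before the ratio.  The ratio is
    (ip + eps) / (input + eps) with pseudocount eps guarding zero input, and
    is reported as log2(fold + 1).
    """
    if set(ip.cpm.index) != set(input_.cpm.index):
        raise ValueError("IP and input isoacceptor sets differ")
    inp = input_.cpm.loc[ip.cpm.index]

    def ratio(num: float, den: float) -> float:
        if den + pseudocount == 0:
            return 0.0  # no signal on either side (only possible at eps = 0)
        return (num + pseudocount) / (den + pseudocount)

    rows = []
    for iso in ip.cpm.index:
        pre_ip = float(ip.cpm.loc[iso, list(PREMATURE_BINS)].sum())
        pre_in = float(inp.loc[iso, list(PREMATURE_BINS)].sum())
        mat_ip = float(ip.cpm.loc[iso, "CCA"])
        mat_in = float(inp.loc[iso, "CCA"])
        pre_fold = ratio(pre_ip, pre_in)
        mat_fold = ratio(mat_ip, mat_in)
        rows.append({
            "isoacceptor": iso,
            "premature_ip_cpm": pre_ip, "premature_input_cpm": pre_in,
            "mature_ip_cpm": mat_ip, "mature_input_cpm": mat_in,
            "premature_log2p1_fold": float(np.log2(pre_fold + 1)),
            "mature_log2p1_fold": float(np.log2(mat_fold + 1)),
        })
    return pd.DataFrame(rows).set_index("isoacceptor")


def cumulative_tail_table(cpm: CPMTable, by_length: bool = False) -> pd.DataFrame:
    """log10(1 + cumulative premature CPM) per isoacceptor per tail length.

    Default convention is >=-length: the entry at Un accumulates CPM of all
    tails of length >= n, making rows non-increasing in tail length.
    ``by_length=True`` reports the ==-length (non-cumulative) variant.
    """
    pre = cpm.cpm[list(PREMATURE_BINS)]
    if by_length:
        cum = pre
    else:
        cum = pre.iloc[:, ::-1].cumsum(axis=1).iloc[:, ::-1]
    return np.log10(1.0 + cum)


LOG10_2 = float(np.log10(2.0))


def tail_presence(cpm: CPMTable, threshold: float = LOG10_2) -> pd.DataFrame:
    """Boolean isoacceptor x tail-length matrix: present iff CPM > threshold.

    The default threshold 0.3 CPM (log10 of 2) scores a tail length as
    present only above sporadic-read background; the inequality is strict.
    """
    return cpm.cpm[list(PREMATURE_BINS)] > threshold


def presence_anova(wt: Sequence[pd.DataFrame],
                   ko: Sequence[pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Two-way ANOVA (condition x tail length) on per-replicate presence counts.

    The response is the number of isoacceptors scored present at each tail
    length in each replicate.  Returns the type-II ANOVA table plus
    Bonferroni-adjusted per-tail-length condition comparisons (each raw p
    multiplied by the number of tail lengths).
    """
    if len(wt) < 2 or len(ko) < 2:
        raise ValueError("need >= 2 replicates per condition")
    rows = []
    for cond, reps in (("WT", wt), ("KO", ko)):
        for i, mat in enumerate(reps):
            for tail in PREMATURE_BINS:
                rows.append({"condition": cond, "tail": tail,
                             "replicate": f"{cond}{i + 1}",
                             "n_present": int(mat[tail].sum())})
    table = pd.DataFrame(rows)
    anova = two_way_anova(table, "n_present", "condition", "tail")
    per_tail = bonferroni_by_level(table, "n_present", "condition", "tail")
    return {"anova": anova, "per_tail": per_tail, "long": table}


def copy_number_correlation(cpm_per_isotype: Mapping[str, float],
                            gene_copies_per_isotype: Mapping[str, int],
                            ) -> tuple[float, float]:
    """Pearson r of log2(CPM) vs genomic gene-copy number across isotypes."""
    keys = sorted(set(cpm_per_isotype) & set(gene_copies_per_isotype))
    if len(keys) < 3:
        raise ValueError("need >= 3 shared isotypes")
    return pearson_log2([cpm_per_isotype[k] for k in keys],
                        [gene_copies_per_isotype[k] for k in keys],
                        log_x=True, log_y=False)


def enrichment_vs_trailer(enrichment: pd.DataFrame,
                          trailer_means: Mapping[str, float]) -> tuple[float, float]:
    """Pearson r of premature log2(fold+1) enrichment vs mean genomic trailer
    length, matched on isoacceptor/isotype keys."""
    keys = sorted(set(enrichment.index) & set(trailer_means))
    if len(keys) < 3:
        raise ValueError("need >= 3 matched isotypes")
    return pearson_log2(
        enrichment.loc[keys, "premature_log2p1_fold"].to_numpy(float),
        [trailer_means[k] for k in keys], log_x=False, log_y=False)


def bin_counts_long(tables: Sequence[BinCountTable],
                    cpms: Sequence[CPMTable]) -> pd.DataFrame:
    """Long-format (replicate, isoacceptor, bin, count, cpm) export table."""
    rows = []
    for raw, norm in zip(tables, cpms):
        for iso in raw.counts.index:
            for b in TAIL_BINS:
                rows.append({"replicate": raw.replicate, "isoacceptor": iso,
                             "bin": b, "count": int(raw.counts.loc[iso, b]),
                             "cpm": float(norm.cpm.loc[iso, b])})
    return pd.DataFrame(rows)
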