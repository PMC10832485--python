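"""Lightweight full-length 16S rRNA community profiling.

The stage chain mirrors a standard long-read (PacBio CCS) amplicon
workflow at desk scale: exact-match barcode demultiplexing (16-base
tags ligated to both ends), joint length/predicted-accuracy QC
(1400-1800 bp inclusive, accuracy >= 0.90), exact dereplication at
100 % identity, abundance-sorted greedy centroid clustering into OTUs at
97 % identity, relative-abundance and dominant-taxa reporting, Shannon
diversity and rarefaction by seeded subsampling without replacement.

The OTU clusterer is a from-first-principles greedy centroid scheme in
the UCLUST style: queries are processed in decreasing abundance (ties by
sequence) and join the first existing centroid whose global-alignment
identity reaches the threshold, else found a new centroid. Identity is
matches / alignment columns under Needleman-Wunsch with match +1,
mismatch -1, linear gap -2, terminal gaps penalized. Chimera removal is
a no-op hook (``remove_chimeras``).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from skbio.diversity.alpha import shannon as _skbio_shannon

__all__ = [
    "AmpliconRead",
    "QCStats",
    "UniqueSequence",
    "OTU",
    "OTUTable",
    "CommunityError",
    "read_fastq_with_accuracy",
    "demultiplex",
    "qc_filter",
    "dereplicate",
    "alignment_identity",
    "cluster_otus",
    "remove_chimeras",
    "relative_abundance",
    "dominant_taxa",
    "shannon",
    "rarefaction",
]

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHN", "TGCAYRMKVBHDN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CommunityError(ValueError):
    """Raised on malformed community-profiling inputs."""


@dataclass
class AmpliconRead:
    """One CCS amplicon read with its per-read predicted accuracy."""

    read_id: str
    sequence: str
    accuracy: float
    sample_id: str | None = None
    barcode: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CommunityError(f"read {self.read_id!r} has empty sequence")
        if not (0.0 <= self.accuracy <= 1.0):
            raise CommunityError(
                f"read {self.read_id!r} accuracy {self.accuracy} outside [0, 1]"
            )


@dataclass
class QCStats:
    n_input: int = 0
    n_passed: int = 0
    n_fail_short: int = 0
    n_fail_long: int = 0
    n_fail_accuracy: int = 0


@dataclass
class UniqueSequence:
    """A dereplicated sequence with its per-sample abundance."""

    sequence: str
    size: int
    rep_id: str
    sample_counts: Counter = field(default_factory=Counter)
    read_ids: list[str] = field(default_factory=list)


@dataclass
class OTU:
    otu_id: str
    representative: str
    size: int
    sample_counts: Counter
    members: list[UniqueSequence]
    taxon: str | None = None


@dataclass
class OTUTable:
    otus: list[OTU]

    def to_dataframe(self) -> pd.DataFrame:
        samples = sorted({s for o in self.otus for s in o.sample_counts})
        rows = []
        for o in self.otus:
            row = {"otu_id": o.otu_id, "rep_length": len(o.representative),
                   "taxon": o.taxon}
            row.update({s: o.sample_counts.get(s, 0) for s in samples})
            rows.append(row)
        return pd.DataFrame(rows)

    def counts_matrix(self) -> pd.DataFrame:
        """OTU x sample integer count matrix."""
        samples = sorted({s for o in self.otus for s in o.sample_counts})
        data = {
            o.otu_id: [o.sample_counts.get(s, 0) for s in samples] for o in self.otus
        }
        return pd.DataFrame(data, index=samples).T


def read_fastq_with_accuracy(fastq_path, sidecar_path) -> list[AmpliconRead]:
    """Load reads from FASTQ plus a ``read_id<TAB>accuracy`` sidecar TSV."""
    acc = pd.read_csv(sidecar_path, sep="\t", header=None,
                      names=["read_id", "accuracy"])
    acc_map = dict(zip(acc["read_id"], acc["accuracy"]))
    reads = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        if rec.id not in acc_map:
            raise CommunityError(f"no accuracy entry for read {rec.id!r}")
        reads.append(AmpliconRead(rec.id, str(rec.seq).upper(), float(acc_map[rec.id])))
    return reads


def demultiplex(
    reads: list[AmpliconRead], barcode_map: dict[str, str]
) -> tuple[dict[str, list[AmpliconRead]], int]:
    """Assign reads to samples by exact 5' 16-mer barcode match.

    The barcode (and its reverse complement at the 3' end, when present)
    is stripped from assigned reads. Returns per-sample read lists plus
    the count of unassigned reads. No mismatch tolerance.
    """
    for bc in barcode_map:
        if len(bc) != 16:
            raise CommunityError(f"barcode {bc!r} is not 16 bases")
    if len(set(barcode_map)) != len(barcode_map):
        raise CommunityError("duplicate barcodes in map")

    by_sample: dict[str, list[AmpliconRead]] = {s: [] for s in barcode_map.values()}
    unassigned = 0
    for read in reads:
        prefix = read.sequence[:16]
        sample = barcode_map.get(prefix)
        if sample is None:
            unassigned += 1
            continue
        seq = read.sequence[16:]
        tail = _revcomp(prefix)
        if seq.endswith(tail) or seq.endswith(prefix):
            seq = seq[:-16]
        by_sample[sample].append(
            AmpliconRead(read.read_id, seq, read.accuracy, sample, prefix)
        )
    return by_sample, unassigned


def qc_filter(
    reads: list[AmpliconRead],
    min_len: int = 1400,
    max_len: int = 1800,
    min_acc: float = 0.90,
) -> tuple[list[AmpliconRead], QCStats]:
    """Keep reads with min_len <= length <= max_len and accuracy >= min_acc.

    Both length bounds are inclusive; the accuracy bound is inclusive.
    A read failing both length and accuracy is counted under its length
    reason.
    """
    if min_len <= 0 or max_len <= 0 or min_len > max_len:
        raise CommunityError(f"bad length window [{min_len}, {max_len}]")
    stats = QCStats(n_input=len(reads))
    survivors = []
    for read in reads:
        n = len(read.sequence)
        if n < min_len:
            stats.n_fail_short += 1
        elif n > max_len:
            stats.n_fail_long += 1
        elif read.accuracy < min_acc:
            stats.n_fail_accuracy += 1
        else:
            stats.n_passed += 1
            survivors.append(read)
    return survivors, stats


def dereplicate(reads: list[AmpliconRead]) -> list[UniqueSequence]:
    """Group reads by exact sequence identity (100 % clustering).

    The representative is the first-seen read; output preserves
    first-seen order. Sizes sum to the input read count.
    """
    uniques: dict[str, UniqueSequence] = {}
    for read in reads:
        u = uniques.get(read.sequence)
        if u is None:
            u = UniqueSequence(read.sequence, 0, read.read_id)
            uniques[read.sequence] = u
        u.size += 1
        u.read_ids.append(read.read_id)
        if read.sample_id is not None:
            u.sample_counts[read.sample_id] += 1
    return list(uniques.values())


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Needleman-Wunsch with match +1, mismatch -1, linear gap -2; terminal
    gaps are penalized like internal ones.
    """
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


def cluster_otus(
    uniques: list[UniqueSequence],
    identity: float = 0.97,
    taxon_of: dict[str, str] | None = None,
) -> OTUTable:
    """Abundance-sorted greedy centroid clustering at a fixed identity.

    Queries are taken in decreasing size (ties by sequence, then
    lexicographic); each joins the first centroid — in founding order —
    reaching the identity threshold, else founds a new centroid. When
    ``taxon_of`` maps read ids to taxon labels, each OTU is labelled by
    the majority taxon of its member reads.
    """
    if not (0 < identity <= 1):
        raise CommunityError(f"identity must be in (0, 1], got {identity}")
    ordered = sorted(uniques, key=lambda u: (-u.size, u.sequence))
    otus: list[OTU] = []
    for query in ordered:
        placed = False
        for otu in otus:
            if alignment_identity(query.sequence, otu.representative) >= identity:
                otu.size += query.size
                otu.sample_counts.update(query.sample_counts)
                otu.members.append(query)
                placed = True
                break
        if not placed:
            otus.append(
                OTU(
                    otu_id=f"OTU{len(otus) + 1}",
                    representative=query.sequence,
                    size=query.size,
                    sample_counts=Counter(query.sample_counts),
                    members=[query],
                )
            )
    if taxon_of is not None:
        for otu in otus:
            labels = Counter(
                taxon_of[rid]
                for m in otu.members for rid in m.read_ids
                if rid in taxon_of
            )
            if labels:
                otu.taxon = labels.most_common(1)[0][0]
    return OTUTable(otus)


def remove_chimeras(uniques: list[UniqueSequence]) -> list[UniqueSequence]:
    """Chimera-removal hook. Deliberately a no-op in this toolkit."""
    return uniques


def relative_abundance(
    counts: pd.DataFrame | OTUTable, rank_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-sample relative abundance (%) of taxa (or OTUs).

    ``counts`` is a taxa x sample count matrix or an :class:`OTUTable`
    (rows collapsed by OTU taxon when labels are present). ``rank_of``
    optionally maps row labels to a coarser rank (e.g. species ->
    genus); rows mapping to the same label are summed. Columns each sum
    to 100; an all-zero sample raises :class:`CommunityError`. A row
    ``mean_pct`` (average contribution across samples) is appended as a
    column in the result.
    """
    if isinstance(counts, OTUTable):
        mat = counts.counts_matrix()
        labels = [o.taxon if o.taxon is not None else o.otu_id for o in counts.otus]
        mat.index = labels
        mat = mat.groupby(level=0).sum()
    else:
        mat = counts.copy()
    if rank_of is not None:
        mat = mat.groupby(mat.index.map(lambda t: rank_of.get(t, t))).sum()
    totals = mat.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise CommunityError(f"samples with zero total counts: {list(zero.index)}")
    rel = 100.0 * mat / totals
    rel["mean_pct"] = rel.mean(axis=1)
    return rel


def dominant_taxa(
    report: pd.DataFrame | pd.Series | dict, min_pct: float = 1.0
) -> tuple[pd.Series, float]:
    """Taxa strictly above ``min_pct`` relative abundance, descending.

    Accepts a per-sample percentage Series/dict, or the frame from
    :func:`relative_abundance` (the ``mean_pct`` column is used).
    Returns the ordered dominant series and the cumulative percentage.
    """
    if isinstance(report, pd.DataFrame):
        series = report["mean_pct"]
    else:
        series = pd.Series(report, dtype=float)
    dominant = series[series > min_pct].sort_values(ascending=False)
    return dominant, float(dominant.sum())


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    arr = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                     dtype=float)
    if arr.sum() <= 0:
        raise CommunityError("Shannon index undefined for an all-zero sample")
    if (arr < 0).any():
        raise CommunityError("negative counts")
    return float(_skbio_shannon(arr[arr > 0].astype(int), base=math.e))


def rarefaction(
    counts,
    depths: list[int],
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefaction curve by subsampling without replacement.

    ``counts`` are per-OTU counts for one sample. For each depth the
    observed OTU richness is averaged over ``n_reps`` seeded draws.
    Returns columns ``depth, mean_otus, sd_otus``.
    """
    arr = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                     dtype=int)
    total = int(arr.sum())
    if n_reps < 1:
        raise CommunityError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(arr.size), arr)
    rows = []
    for depth in depths:
        if depth > total:
            raise CommunityError(f"depth {depth} exceeds sample total {total}")
        if depth < 1:
            raise CommunityError("depth must be >= 1")
        observed = np.empty(n_reps)
        for r in range(n_reps):
            draw = rng.choice(pool, size=depth, replace=False)
            observed[r] = np.unique(draw).size
        rows.append({"depth": depth, "mean_otus": observed.mean(),
                     "sd_otus": observed.std()})
    return pd.DataFrame(rows)
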