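"""Consensus gene calling across predictor tracks and genome sequence stats.

Independent gene callers agree well on stop codons but scatter on start
choice, so candidate calls are grouped by (strand, stop anchor) and a group
is accepted when at least ``min_support`` distinct tools report it. The
consensus start is the most frequent start among the group's members, ties
broken in favour of the longest CDS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .records import CdsFeature, GenomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

START_CODONS = ("ATG", "TTG", "GTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SequenceStats:
    gc_percent: float
    cds_count_forward: int
    cds_count_reverse: int
    start_codon_fractions: dict[str, float]
    stop_codon_fractions: dict[str, float]
    cds_density_percent: float

    @property
    def cds_count(self) -> int:
        return self.cds_count_forward + self.cds_count_reverse


def consensus_cds(tracks: list[list[CdsFeature]], min_support: int = 3) -> list[CdsFeature]:
    """Vote CDS predictions across tools.

    Predictions from all tracks are grouped by (strand, stop_anchor); a group
    supported by at least ``min_support`` distinct tracks yields one consensus
    feature. Overlapping same-strand predictions with different stop anchors
    stay distinct candidates (no merging). Output is sorted by start.
    """
    if len(tracks) < min_support:
        raise ValueError(
            f"need at least min_support={min_support} tracks, got {len(tracks)}"
        )
    groups: dict[tuple, list[tuple[int, CdsFeature]]] = {}
    for t, track in enumerate(tracks):
        for f in track:
            groups.setdefault(f.key(), []).append((t, f))

    out: list[CdsFeature] = []
    for (strand, _anchor), members in groups.items():
        support = len({t for t, _ in members})
        if support < min_support:
            continue
        counts = Counter(f.cds_start for _, f in members)
        best_count = max(counts.values())
        candidates = [f for _, f in members if counts[f.cds_start] == best_count]
        chosen = max(candidates, key=lambda f: f.length())
        out.append(
            CdsFeature(
                start=chosen.start,
                end=chosen.end,
                strand=strand,
                support=support,
                source="consensus",
            )
        )
    out.sort(key=lambda f: (f.start, f.end, f.strand))
    return out


def _codon(genome: str, f: CdsFeature, which: str) -> str:
    """First (start) or last (stop) codon of a feature, read on the coding strand."""
    if f.end > len(genome) or f.start < 1:
        raise ValueError(
            f"feature {f.start}..{f.end} ({f.strand}) out of bounds for "
            f"genome of length {len(genome)}"
        )
    sub = genome[f.start - 1 : f.end]
    if f.strand == "-":
        sub = sub.translate(_COMPLEMENT)[::-1]
    return sub[:3] if which == "start" else sub[-3:]


def _union_length(features: list[CdsFeature]) -> int:
    if not features:
        return 0
    ivs = sorted((f.start, f.end) for f in features)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e + 1:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s + 1)


def sequence_stats(genome: GenomeRecord, features: list[CdsFeature]) -> SequenceStats:
    """GC%, per-strand CDS counts, start/stop codon usage, and CDS density.

    GC is (G+C)/(A+C+G+T), excluding ambiguity codes from the denominator;
    density is the interval union of CDS spans over genome length; codon
    fractions are read off the genome respecting strand.
    """
    seq = genome.sequence.upper()
    counts = Counter(seq)
    acgt = sum(counts[b] for b in "ACGT")
    gc = 100.0 * (counts["G"] + counts["C"]) / acgt if acgt else 0.0

    fwd = sum(1 for f in features if f.strand == "+")
    rev = len(features) - fwd

    start_counts: Counter = Counter()
    stop_counts: Counter = Counter()
    for f in features:
        sc = _codon(seq, f, "start")
        start_counts[sc if sc in START_CODONS else "other"] += 1
        stop_counts[_codon(seq, f, "stop")] += 1

    n = len(features)
    start_fracs = {
        c: round(100.0 * start_counts[c] / n, 1) if n else 0.0
        for c in (*START_CODONS, "other")
    }
    stop_fracs = {
        c: round(100.0 * stop_counts[c] / n, 1) if n else 0.0
        for c in (*STOP_CODONS,)
    }
    density = 100.0 * _union_length(features) / len(seq) if len(seq) else 0.0
    return SequenceStats(
        gc_percent=round(gc, 1),
        cds_count_forward=fwd,
        cds_count_reverse=rev,
        start_codon_fractions=start_fracs,
        stop_codon_fractions=stop_fracs,
        cds_density_percent=round(density, 1),
    )
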