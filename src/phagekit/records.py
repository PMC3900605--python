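"""Core record types shared across the pipeline.

Coordinates throughout the package are 1-based inclusive (GFF3 convention);
sequences are uppercase nucleotide strings unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GenomeRecord:
    """A nucleotide sequence with an identifier and assumed topology.

    Parameters
    ----------
    id : str
        Unique genome identifier (FASTA header token).
    sequence : str
        Uppercase nucleotide sequence.
    circular : bool
        Whether the assembly is treated as circular. Collapsed assemblies of
        linear genomes with long terminal repeats present as circular.
    features : list
        Optional feature annotations attached downstream.
    """

    id: str
    sequence: str
    circular: bool = False
    features: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CdsFeature:
    """A protein-coding feature on a genome.

    ``stop_anchor`` is the genomic coordinate of the last base of the stop
    codon on the coding strand: ``end`` for ``+`` features, ``start`` for
    ``-`` features. Gene callers disagree on start choice far more than on
    the stop, so the anchor is the natural grouping key for consensus voting.
    """

    start: int
    end: int
    strand: str
    support: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def stop_anchor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def cds_start(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end

    def length(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple:
        return (self.strand, self.stop_anchor)
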