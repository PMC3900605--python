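"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure of modular tailed-phage
genomes: groups of genomes sharing syntenic core modules (packaging, head,
tail, replication) that diverge by point substitution, mosaic accessory genes
that turn over wholesale, linear genomes whose identical terminal repeats
collapse into a circular assembly with doubled read depth, protein marker
families evolved on a known tree, multi-tool CDS prediction tracks with
per-tool error rates, and noisy adsorption / one-step-growth titre series.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import dendropy
import numpy as np

from .kinetics import TiterSeries
from .records import CdsFeature, GenomeRecord
from .structure import CoverageProfile

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


# ---------------------------------------------------------------------------
# low-level sequence helpers


def _random_nt(rng: np.random.Generator, length: int) -> np.ndarray:
    return NUCLEOTIDES[rng.integers(0, 4, size=length)]


def _random_coding(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random sense-codon sequence of exactly ``length`` bases (no in-frame stops)."""
    n_codons = (length + 2) // 3
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    seq = "".join(SENSE_CODONS[i] for i in idx)[:length]
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def mutate_sites(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. per-site substitution: each site is replaced, with probability
    ``rate``, by a uniformly chosen *different* base. No indels."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hit):
        # shift by 1..3 in base-index space guarantees a different base
        cur = np.searchsorted(NUCLEOTIDES, out[hit])
        out[hit] = NUCLEOTIDES[(cur + rng.integers(1, 4, size=len(hit))) % 4]
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical sites between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.mean(x == y))


# ---------------------------------------------------------------------------
# modular phage community


@dataclass
class CommunityConfig:
    """Design of a synthetic phage community.

    ``module_plan`` lists the conserved core modules in syntenic order with
    their lengths (P=packaging, H=head, T=tail, R=replication). Accessory
    genes of ``accessory_length`` bp are interleaved between consecutive core
    modules and are replaced wholesale with probability
    ``accessory_turnover`` per genome, emulating mosaic variable regions.
    """

    n_groups: int = 3
    genomes_per_group: int = 4
    module_plan: tuple = (("P", 450), ("H", 450), ("T", 450), ("R", 450))
    within_rate: float = 0.05
    between_rate: float = 0.45
    accessory_turnover: float = 0.5
    accessory_length: int = 300
    outgroup: bool = True
    outgroup_branch: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.between_rate > self.within_rate >= 0:
            raise ValueError(
                f"between_rate ({self.between_rate}) must exceed "
                f"within_rate ({self.within_rate}) >= 0"
            )
        for name, length in self.module_plan:
            if length < 300:
                raise ValueError(f"module {name!r} shorter than 300 bp")


@dataclass
class CommunityTruth:
    """Generated genomes plus the ground truth behind them."""

    genomes: list[GenomeRecord]
    group_labels: dict[str, str]
    generating_tree: dendropy.Tree
    config: CommunityConfig = None

    def group_of(self, genome_id: str) -> str:
        return self.group_labels[genome_id]


def _group_name(i: int) -> str:
    return "G" + string.ascii_uppercase[i]


def simulate_phage_community(config: CommunityConfig) -> CommunityTruth:
    """Generate groups of modular genomes with conserved core synteny.

    One root ancestor is drawn with coding-like core modules; each group's
    ancestor is a mutated copy at ``between_rate`` substitutions/site, and
    group members are mutated copies of their group ancestor at
    ``within_rate``. Core module order is identical in every in-group genome;
    accessory genes are independently replaced by unrelated random sequence
    with probability ``accessory_turnover``. The optional outgroup genome is
    drawn fresh and shares no ancestry with the rest.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    core = [_random_coding(rng, length) for _, length in cfg.module_plan]
    n_acc = max(0, len(cfg.module_plan) - 1)
    accessory = [_random_nt(rng, cfg.accessory_length) for _ in range(n_acc)]

    def assemble(mods: list[np.ndarray], accs: list[np.ndarray]) -> str:
        parts = []
        for i, m in enumerate(mods):
            parts.append(m)
            if i < len(accs):
                parts.append(accs[i])
        return np.concatenate(parts).tobytes().decode()

    genomes: list[GenomeRecord] = []
    labels: dict[str, str] = {}
    for g in range(cfg.n_groups):
        gname = _group_name(g)
        anc_core = [mutate_sites(m, cfg.between_rate, rng) for m in core]
        anc_acc = [mutate_sites(a, cfg.between_rate, rng) for a in accessory]
        for k in range(cfg.genomes_per_group):
            mods = [mutate_sites(m, cfg.within_rate, rng) for m in anc_core]
            accs = []
            for a in anc_acc:
                if rng.random() < cfg.accessory_turnover:
                    accs.append(_random_nt(rng, cfg.accessory_length))
                else:
                    accs.append(mutate_sites(a, cfg.within_rate, rng))
            gid = f"{gname}_{k + 1}"
            genomes.append(GenomeRecord(id=gid, sequence=assemble(mods, accs)))
            labels[gid] = gname

    if cfg.outgroup:
        total_len = len(genomes[0].sequence)
        genomes.append(
            GenomeRecord(id="outgroup", sequence=_random_nt(rng, total_len).tobytes().decode())
        )
        labels["outgroup"] = "outgroup"

    tree = _community_tree(cfg, [g.id for g in genomes], labels)
    return CommunityTruth(genomes=genomes, group_labels=labels, generating_tree=tree, config=cfg)


def _community_tree(
    cfg: CommunityConfig, ids: list[str], labels: dict[str, str]
) -> dendropy.Tree:
    """Tree that generated the community: a radiation of group clades."""
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    groups: dict[str, list[str]] = {}
    for gid in ids:
        groups.setdefault(labels[gid], []).append(gid)
    for gname, members in groups.items():
        if gname == "outgroup":
            leaf = tree.seed_node.new_child(edge_length=cfg.outgroup_branch)
            leaf.taxon = taxa.get_taxon(members[0])
            continue
        gnode = tree.seed_node.new_child(edge_length=cfg.between_rate)
        for gid in members:
            leaf = gnode.new_child(edge_length=cfg.within_rate)
            leaf.taxon = taxa.get_taxon(gid)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# collapsed assembly with long terminal repeats


@dataclass
class AssemblyTruth:
    """Ground truth of a simulated collapsed assembly (1-based inclusive)."""

    ltr_start: int
    ltr_end: int
    ltr_length: int
    unique_length: int
    genome_length: int
    n_reads: int
    read_length: int


def simulate_collapsed_assembly(
    genome_length: int,
    ltr_length: int,
    n_reads: int,
    read_length: int,
    seed: int = 0,
) -> tuple[GenomeRecord, CoverageProfile, AssemblyTruth]:
    """Simulate shotgun coverage of a linear genome with identical terminal
    repeats, mapped onto its collapsed circular representation.

    The linear genome has its first and last ``ltr_length`` bases identical;
    the collapsed form keeps one repeat copy, so reads from either copy map
    onto it and the repeat shows ~2x depth. Reads are sampled uniformly from
    the linear molecule (so depth ramps down over one read length at the two
    physical ends, which both map inside the collapsed repeat).
    """
    if ltr_length >= genome_length / 2:
        raise ValueError("ltr_length must be < genome_length / 2")
    if read_length >= ltr_length:
        raise ValueError(
            "read_length must be < ltr_length (reads spanning a full repeat "
            "copy would map ambiguously)"
        )
    rng = np.random.default_rng(seed)
    unique_length = genome_length - ltr_length
    collapsed = _random_nt(rng, unique_length)
    # linear molecule = collapsed + second copy of the leading repeat
    depth_diff = np.zeros(unique_length + 1, dtype=np.int64)
    if n_reads > 0:
        starts = rng.integers(0, genome_length - read_length + 1, size=n_reads)
        s = np.where(starts >= unique_length, starts - unique_length, starts)
        e = s + read_length
        wrap = e > unique_length
        np.add.at(depth_diff, s, 1)
        np.add.at(depth_diff, np.minimum(e, unique_length), -1)
        if wrap.any():
            depth_diff[0] += int(wrap.sum())
            np.add.at(depth_diff, e[wrap] - unique_length, -1)
    depth = np.cumsum(depth_diff[:-1])

    record = GenomeRecord(
        id=f"collapsed_assembly_seed{seed}",
        sequence=collapsed.tobytes().decode(),
        circular=True,
    )
    truth = AssemblyTruth(
        ltr_start=1,
        ltr_end=ltr_length,
        ltr_length=ltr_length,
        unique_length=unique_length,
        genome_length=genome_length,
        n_reads=n_reads,
        read_length=read_length,
    )
    return record, CoverageProfile(depth=depth.astype(float)), truth


# ---------------------------------------------------------------------------
# protein marker families on a tree


def simulate_marker_families(
    tree: dendropy.Tree,
    n_markers: int,
    site_counts: int | list[int],
    rate_scale: float | list[float],
    seed: int = 0,
) -> list[dict[str, str]]:
    """Evolve aligned protein marker families independently along one tree.

    Each marker starts from a random root sequence; along every branch a
    Poisson(branch_length * rate_scale * n_sites) number of substitutions is
    applied at random positions, each replacing the residue with a uniformly
    chosen different amino acid (20-state Jukes-Cantor-style process, no
    indels, so the family is aligned by construction). Returns one
    {tip_label: sequence} mapping per marker.
    """
    if isinstance(site_counts, int):
        site_counts = [site_counts] * n_markers
    if isinstance(rate_scale, (int, float)):
        rate_scale = [float(rate_scale)] * n_markers
    if len(site_counts) != n_markers or len(rate_scale) != n_markers:
        raise ValueError("site_counts / rate_scale must match n_markers")

    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    aa_index = {c: i for i, c in enumerate(aa)}
    markers = []
    for m in range(n_markers):
        length, rate = site_counts[m], rate_scale[m]
        root_seq = aa[rng.integers(0, 20, size=length)]
        seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
        family: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                parent_seq = root_seq
            else:
                parent_seq = seqs[id(node.parent_node)]
                bl = node.edge.length or 0.0
                n_subs = rng.poisson(bl * rate * length) if rate > 0 and bl > 0 else 0
                child = parent_seq.copy()
                if n_subs:
                    pos = rng.integers(0, length, size=n_subs)
                    for p in pos:
                        cur = aa_index[child[p]]
                        child[p] = aa[(cur + rng.integers(1, 20)) % 20]
                seqs[id(node)] = child
                parent_seq = child
            if node.is_leaf():
                family[node.taxon.label] = parent_seq.tobytes().decode()
        markers.append(family)
    return markers


# ---------------------------------------------------------------------------
# gene-predictor tracks


def simulate_predictor_tracks(
    genome: GenomeRecord,
    true_cds: list[CdsFeature],
    sensitivities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0),
    fp_rate: float | tuple[float, ...] = 0.0,
    start_jitter: int = 0,
    seed: int = 0,
) -> list[list[CdsFeature]]:
    """Emulate the outputs of several independent gene callers.

    Each tool reports each true CDS with its own sensitivity; reported starts
    are jittered downstream by a random multiple of 3 up to ``start_jitter``
    bp (callers disagree on start choice, not on the stop: stop position and
    strand are always preserved). False features are added at ``fp_rate``
    calls per kb, independently per tool.
    """
    if isinstance(fp_rate, (int, float)):
        fp_rate = tuple(float(fp_rate) for _ in sensitivities)
    if len(fp_rate) != len(sensitivities):
        raise ValueError("fp_rate must match sensitivities in length")
    rng = np.random.default_rng(seed)
    L = len(genome.sequence)
    tracks: list[list[CdsFeature]] = []
    for t, (sens, fp) in enumerate(zip(sensitivities, fp_rate)):
        name = f"tool{t + 1}"
        track: list[CdsFeature] = []
        for f in true_cds:
            if rng.random() >= sens:
                continue
            start, end = f.start, f.end
            if start_jitter >= 3 and f.length() > start_jitter + 30:
                delta = 3 * int(rng.integers(0, start_jitter // 3 + 1))
                if f.strand == "+":
                    start += delta
                else:
                    end -= delta
            track.append(CdsFeature(start=start, end=end, strand=f.strand, source=name))
        n_fp = rng.poisson(fp * L / 1000.0) if fp > 0 else 0
        for _ in range(n_fp):
            length = 3 * int(rng.integers(30, 201))
            start = int(rng.integers(1, max(2, L - length)))
            strand = "+" if rng.random() < 0.5 else "-"
            track.append(
                CdsFeature(start=start, end=start + length - 1, strand=strand, source=name)
            )
        track.sort(key=lambda f: (f.start, f.end, f.strand))
        tracks.append(track)
    return tracks


# ---------------------------------------------------------------------------
# titre series


@dataclass
class AdsorptionParams:
    """Free-phage decay P(t) = p0 * exp(-k * b * t)."""

    p0: float = 3.0e6  # initial free phage, PFU/ml (MOI 0.01 at b=3e8)
    k: float = 6.44e-9  # adsorption rate constant, ml/min
    b: float = 3.0e8  # host cell density, CFU/ml

    def __post_init__(self) -> None:
        if min(self.p0, self.k, self.b) <= 0:
            raise ValueError("adsorption parameters must be positive")


@dataclass
class OneStepParams:
    """Step model of a one-step growth experiment.

    Total (untreated) titre stays at ``n0`` infective centres until the
    latent period; lysis times scatter around it, so a fraction
    ``onset_release`` of the eventual rise appears at the latent time itself,
    and the titre then ramps linearly over ``rise_min`` minutes to the
    plateau ``burst * n0``. The chloroform-treated series follows the same
    shape but rises at the eclipse period from a residual free-phage
    baseline.
    """

    n0: float = 3.0e5  # initial infective centres, PFU/ml (MOI 0.001 at 3e8)
    burst: float = 153.0
    latent_min: float = 35.0
    eclipse_min: float = 25.0
    rise_min: float = 25.0
    residual_fraction: float = 0.1
    onset_release: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n0, self.burst, self.latent_min, self.eclipse_min, self.rise_min) <= 0:
            raise ValueError("one-step parameters must be positive")
        if self.eclipse_min > self.latent_min:
            raise ValueError("eclipse period cannot exceed latent period")


@dataclass
class SeriesDesign:
    """Sampling design: time points (minutes), replicates, lognormal noise CV."""

    times: tuple = tuple(range(0, 11))
    replicates: int = 4
    cv: float = 0.1

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.cv < 0:
            raise ValueError("invalid design")


ADSORPTION_DESIGN = SeriesDesign(times=tuple(range(0, 11)), replicates=4, cv=0.1)
ONE_STEP_DESIGN = SeriesDesign(times=tuple(range(0, 81, 10)), replicates=4, cv=0.1)


def _noisy(values: np.ndarray, design: SeriesDesign, rng: np.random.Generator) -> np.ndarray:
    """Replicate matrix with mean-preserving multiplicative lognormal noise."""
    out = np.tile(values, (design.replicates, 1)).astype(float)
    if design.cv > 0:
        sigma = np.sqrt(np.log1p(design.cv**2))
        out *= np.exp(sigma * rng.standard_normal(out.shape) - sigma**2 / 2)
    return out


def _one_step_curve(
    t: np.ndarray,
    baseline: float,
    plateau: float,
    onset: float,
    rise: float,
    jump: float = 0.1,
) -> np.ndarray:
    frac = np.where(
        t < onset, 0.0, np.clip(jump + (1.0 - jump) * (t - onset) / rise, 0.0, 1.0)
    )
    return baseline + (plateau - baseline) * frac


def simulate_titer_series(
    kind: str,
    params: AdsorptionParams | OneStepParams,
    design: SeriesDesign | None = None,
    seed: int = 0,
):
    """Generate noisy plaque-count series.

    ``kind='adsorption'`` returns one TiterSeries of exponentially decaying
    free phage. ``kind='one_step'`` returns a (total, chloroform_treated)
    pair on the same time grid.
    """
    rng = np.random.default_rng(seed)
    if kind == "adsorption":
        if not isinstance(params, AdsorptionParams):
            raise TypeError("adsorption kind requires AdsorptionParams")
        design = design or ADSORPTION_DESIGN
        t = np.asarray(design.times, dtype=float)
        truth = params.p0 * np.exp(-params.k * params.b * t)
        return TiterSeries(
            times=t,
            pfu=_noisy(truth, design, rng),
            treatment="total",
            cell_density=params.b,
            moi=params.p0 / params.b,
        )
    if kind == "one_step":
        if not isinstance(params, OneStepParams):
            raise TypeError("one_step kind requires OneStepParams")
        design = design or ONE_STEP_DESIGN
        t = np.asarray(design.times, dtype=float)
        plateau = params.burst * params.n0
        total_truth = _one_step_curve(
            t, params.n0, plateau, params.latent_min, params.rise_min,
            params.onset_release,
        )
        treated_truth = _one_step_curve(
            t, params.n0 * params.residual_fraction, plateau, params.eclipse_min,
            params.rise_min, params.onset_release,
        )
        total = TiterSeries(times=t, pfu=_noisy(total_truth, design, rng), treatment="total")
        treated = TiterSeries(
            times=t, pfu=_noisy(treated_truth, design, rng), treatment="chloroform_treated"
        )
        return total, treated
    raise ValueError(f"unknown kind {kind!r}")
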