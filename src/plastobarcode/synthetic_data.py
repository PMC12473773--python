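"""Synthetic barcode panels with the structure the analysis assumes.

The generator emulates a curated multi-species plastome panel: a Yule species
tree, star-shaped intraspecific variation, K80 (Kimura two-parameter)
sequence evolution with planted rate hotspots, and optional missing data.
Species in the default panel are *diagnosable*: every species pendant edge
gets a floor (a fraction of tree height) so each species carries private
divergence, and the species tree is scaled so that the mean between-species
path equals ``interspecific_depth - intraspecific_depth`` — as the
intraspecific depth approaches the interspecific depth the species signal
vanishes and individuals become exchangeable. The whole genealogy is then
calibrated so the background (multiplier-1) per-site divergence matches
``background_pi``, putting hotspot windows at multiplier x background.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seq_io import LabelledAlignment, SequenceRecord, write_fasta
from .trees import Node, Tree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_LOCUS_LENGTHS = {"P": 6000, "F": 6000, "R": 5000, "Y": 7000}
# one window-sized (800 col) hotspot per locus, step-aligned
DEFAULT_HOTSPOTS = [
    ("P", 2400, 3200, 10.0),
    ("F", 2000, 2800, 10.0),
    ("R", 1600, 2400, 10.0),
    ("Y", 3200, 4000, 10.0),
]


@dataclass
class SimulationConfig:
    n_species: int = 20
    n_individuals: int = 55
    individuals_min: int = 2
    individuals_max: int = 6
    locus_lengths: dict = field(default_factory=lambda: dict(DEFAULT_LOCUS_LENGTHS))
    hotspots: list = field(default_factory=lambda: list(DEFAULT_HOTSPOTS))
    interspecific_depth: float = 0.005
    intraspecific_depth: float = 0.0005
    kappa: float = 2.0
    background_pi: float = 0.0007
    min_species_pendant: float = 0.5
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not (0 <= self.intraspecific_depth <= self.interspecific_depth):
            raise ValueError("require 0 <= intraspecific_depth <= interspecific_depth")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        lo = self.n_species * self.individuals_min
        hi = self.n_species * self.individuals_max
        if not lo <= self.n_individuals <= hi:
            raise ValueError(f"n_individuals must lie in [{lo}, {hi}]")
        for locus, start, end, mult in self.hotspots:
            if locus not in self.locus_lengths:
                raise ValueError(f"hotspot names unknown locus {locus!r}")
            if not (0 <= start < end <= self.locus_lengths[locus]):
                raise ValueError(f"hotspot interval out of bounds for locus {locus!r}")
            if mult < 1:
                raise ValueError("hotspot rate multipliers must be >= 1")


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# ------------------------------------------------------------- tree simulation

def simulate_species_tree(
    n_species: int, depth: float, seed=None, rng: np.random.Generator | None = None
) -> Tree:
    """Ultrametric Yule (pure-birth) tree rescaled to root-to-tip depth.

    Forward simulation at unit birth rate per lineage, with a final waiting
    time after the last speciation so the most recent split is not at the
    present. Tips are named sp01, sp02, ... in tree order.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(seed, rng)
    root = Node()
    start: dict[int, float] = {}
    t = 0.0
    first_split = None
    lineages = [root]
    while len(lineages) < n_species:
        k = len(lineages)
        t += rng.exponential(1.0 / k)
        if first_split is None:
            first_split = t
        idx = int(rng.integers(k))
        node = lineages.pop(idx)
        node.length = t - start.get(id(node), first_split)
        for _ in range(2):
            child = Node()
            start[id(child)] = t
            node.add(child)
            lineages.append(child)
    t_end = t + rng.exponential(1.0 / n_species)
    for leaf in lineages:
        leaf.length = t_end - start.get(id(leaf), first_split)
    tree = Tree(root)
    height = t_end - first_split
    if height > 0 and depth > 0:
        tree.rescale(depth / height)
    elif depth == 0:
        tree.rescale(0.0)
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.name = f"sp{i:02d}"
    tree.root.length = 0.0
    return tree


def attach_individuals(
    species_tree: Tree,
    counts: Mapping[str, int],
    intraspecific_depth: float,
    seed=None,
) -> Tree:
    """Replace each species tip by a star of its individuals.

    Individuals are named ``<species>_<k>``; expected divergence between two
    conspecific individuals equals ``intraspecific_depth`` (pendants of half
    that). A count of one passes the tip through unchanged (renamed).
    """
    tree = species_tree.copy()
    for leaf in tree.leaves():
        c = counts[leaf.name]
        if c < 1:
            raise ValueError(f"count for {leaf.name!r} must be >= 1")
        species = leaf.name
        if c == 1:
            leaf.name = f"{species}_1"
            continue
        leaf.name = None
        for k in range(1, c + 1):
            leaf.add(Node(f"{species}_{k}", intraspecific_depth / 2.0))
    return tree


# ---------------------------------------------------------- sequence evolution

def _k80_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """K80 probability matrix after expected ``t`` substitutions per site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    for s in range(4):
        P[s, s] = p_same
        P[s, (s + 2) % 4] = p_ts  # A<->G, C<->T with coding A0 C1 G2 T3
    return P


def _mutate(
    parent: np.ndarray, t: float, kappa: float, rate_profile: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    child = parent.copy()
    if t <= 0:
        return child
    for rate in np.unique(rate_profile):
        cols = np.flatnonzero(rate_profile == rate)
        P = _k80_transition_matrix(t * float(rate), kappa)
        cum = P.cumsum(axis=1)
        u = rng.random(cols.size)
        for s in range(4):
            sel = parent[cols] == s
            if sel.any():
                child[cols[sel]] = np.searchsorted(cum[s], u[sel], side="right")
    return np.minimum(child, 3)


def evolve_alignment(
    genealogy: Tree,
    length: int,
    kappa: float = 2.0,
    rate_profile: np.ndarray | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
    species_of: Mapping[str, str] | None = None,
) -> LabelledAlignment:
    """Evolve sequences down the genealogy under K80 with per-site rates.

    The root sequence is uniform over {A,C,G,T}; each branch applies the exact
    K80 transition matrix for (branch length x site multiplier) expected
    substitutions per site, so multiple hits genuinely occur.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed, rng)
    if rate_profile is None:
        rate_profile = np.ones(length)
    rate_profile = np.asarray(rate_profile, dtype=float)
    if rate_profile.shape != (length,):
        raise ValueError("rate_profile length must equal alignment length")
    seqs: dict[int, np.ndarray] = {id(genealogy.root): rng.integers(0, 4, size=length, dtype=np.uint8)}
    records: list[SequenceRecord] = []
    for node in genealogy.root.preorder():
        if node is not genealogy.root:
            parent_seq = seqs[id(node.parent)]
            seqs[id(node)] = _mutate(parent_seq, node.length, kappa, rate_profile, rng)
        if node.is_leaf:
            seq = _BASES[seqs[id(node)]].tobytes().decode("ascii")
            species = species_of.get(node.name, "") if species_of else ""
            records.append(SequenceRecord(node.name, seq, species))
    return LabelledAlignment(records)


def inject_missing(
    alignment: LabelledAlignment, missing_fraction: float, seed=None
) -> tuple[LabelledAlignment, np.ndarray]:
    """Replace random cells by 'N' plus a few short '-' runs; returns the mask.

    About 90% of the missing budget goes to independent 'N' cells and 10% to
    gap runs of length 3. The boolean mask marks every injected cell.
    """
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    n, L = alignment.n_records, alignment.length
    mask = np.zeros((n, L), dtype=bool)
    if missing_fraction == 0:
        return alignment, mask
    rng = _rng(seed)
    cells = rng.random((n, L)) < missing_fraction * 0.9
    mask |= cells
    n_runs = int(round(n * L * missing_fraction * 0.1 / 3.0))
    run_len = 3
    for _ in range(n_runs):
        r = int(rng.integers(n))
        c = int(rng.integers(max(L - run_len + 1, 1)))
        mask[r, c : c + run_len] = True
    chars = np.frombuffer(
        "".join(rec.sequence for rec in alignment.records).encode("ascii"), dtype=np.uint8
    ).reshape(n, L).copy()
    chars[cells] = ord("N")
    runs_only = mask & ~cells
    chars[runs_only] = ord("-")
    records = [
        SequenceRecord(rec.sample_id, chars[i].tobytes().decode("ascii"), rec.species, rec.tissue)
        for i, rec in enumerate(alignment.records)
    ]
    return LabelledAlignment(records), mask


# ------------------------------------------------------------------ full panel

@dataclass
class GroundTruth:
    species_tree: str
    genealogy: str
    hotspots: dict
    partition: dict
    scale_factor: float
    mean_background_divergence: float
    config: dict
    missing_cells: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PanelResult:
    loci: dict
    partition: dict
    truth: GroundTruth

    def rate_profile(self, locus: str) -> np.ndarray:
        length = self.loci[locus].length
        profile = np.ones(length)
        for start, end, mult in self.truth.hotspots.get(locus, []):
            profile[start:end] = mult
        return profile


def _allocate_counts(config: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    names = [f"sp{i:02d}" for i in range(1, config.n_species + 1)]
    counts = {name: config.individuals_min for name in names}
    remaining = config.n_individuals - config.individuals_min * config.n_species
    open_names = [n for n in names if counts[n] < config.individuals_max]
    while remaining > 0:
        pick = open_names[int(rng.integers(len(open_names)))]
        counts[pick] += 1
        if counts[pick] >= config.individuals_max:
            open_names.remove(pick)
        remaining -= 1
    return counts


def make_paper_like_panel(config: SimulationConfig | None = None) -> PanelResult:
    """Generate the multi-locus barcode panel plus ground truth.

    Defaults emulate a 55-sample, 20-species panel with four hotspot loci
    (P, F, R, Y), background per-site divergence ~0.0008 and hotspot windows
    around ten times that.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_counts, s_evolve, s_missing = ss.spawn(4)

    species_tree = simulate_species_tree(config.n_species, 1.0, rng=np.random.default_rng(s_tree))
    for leaf in species_tree.leaves():
        leaf.length = max(leaf.length, config.min_species_pendant)
    _, sp_d = species_tree.path_length_matrix()
    mean_species_path = float(sp_d[np.triu_indices(config.n_species, k=1)].mean())
    species_sep = config.interspecific_depth - config.intraspecific_depth
    species_tree.rescale(species_sep / mean_species_path if mean_species_path > 0 else 0.0)

    counts = _allocate_counts(config, np.random.default_rng(s_counts))
    genealogy = attach_individuals(species_tree, counts, config.intraspecific_depth)
    _, d = genealogy.path_length_matrix()
    n = d.shape[0]
    mean_path = float(d[np.triu_indices(n, k=1)].mean())
    scale = config.background_pi / mean_path if mean_path > 0 else 0.0
    genealogy.rescale(scale)

    partition = {leaf: leaf.rsplit("_", 1)[0] for leaf in genealogy.leaf_names()}
    hotspots_by_locus: dict[str, list] = {name: [] for name in config.locus_lengths}
    for locus, start, end, mult in config.hotspots:
        hotspots_by_locus[locus].append((start, end, mult))

    evolve_streams = s_evolve.spawn(len(config.locus_lengths))
    missing_streams = s_missing.spawn(len(config.locus_lengths))
    loci: dict[str, LabelledAlignment] = {}
    missing_cells: dict[str, list] = {}
    for (locus, length), es, ms in zip(config.locus_lengths.items(), evolve_streams, missing_streams):
        profile = np.ones(length)
        for start, end, mult in hotspots_by_locus[locus]:
            profile[start:end] = mult
        aln = evolve_alignment(
            genealogy,
            length,
            kappa=config.kappa,
            rate_profile=profile,
            rng=np.random.default_rng(es),
            species_of=partition,
        )
        if config.missing_fraction > 0:
            aln, mask = inject_missing(aln, config.missing_fraction, seed=ms)
            missing_cells[locus] = [[int(r), int(c)] for r, c in zip(*np.nonzero(mask))]
        else:
            missing_cells[locus] = []
        loci[locus] = aln

    truth = GroundTruth(
        species_tree=species_tree.to_newick(),
        genealogy=genealogy.to_newick(),
        hotspots={k: [list(h) for h in v] for k, v in hotspots_by_locus.items()},
        partition=dict(partition),
        scale_factor=scale,
        mean_background_divergence=config.background_pi,
        config=asdict(config),
        missing_cells=missing_cells,
    )
    return PanelResult(loci=loci, partition=partition, truth=truth)


def write_panel(panel: PanelResult, outdir: str | Path) -> None:
    """Emit <locus>.fa per locus, truth.json and partition.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, aln in panel.loci.items():
        write_fasta(aln.records, outdir / f"{locus}.fa")
    (outdir / "truth.json").write_text(panel.truth.to_json() + "\n")
    with open(outdir / "partition.tsv", "w") as fh:
        fh.write("sample_id\tspecies\n")
        for sid, sp in panel.partition.items():
            fh.write(f"{sid}\t{sp}\n")
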