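"""Simulation of codon alignments on trees under the GY94 model.

Evolution along each branch is simulated event by event (exponential
waiting times under the scaled rate matrix), so the full substitution
history is recorded and available as ground truth for testing ancestral
reconstruction and convergence detection.  Parallel amino-acid
replacements can be planted on chosen branches, re-simulating the affected
site downstream of the forced change.

:func:`bat_fixture` builds the bat-like study fixture: 23 taxa named by
clade (Old-World fruit bats, Rhinolophoidea, Yangochiroptera including a
Miniopterus clade and a tomb bat), 278 codons (834 bp), strong purifying
selection (omega = 0.03, kappa = 3) on a species tree whose major-clade
arrangement follows the accepted bat phylogeny, with planted replacements:
one derived amino acid shared by the fruit-bat stem and the tomb bat, and
two derived amino acids shared by the Miniopterus and Rhinolophoidea stems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .codonseq import CodonAlignment, GeneticCode, standard_code
from .codonmodel import build_q
from .treebuild import read_newick


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedEvent:
    """Force ``derived_codon`` at ``codon_site`` (1-based) at the end of the
    branch above the node labelled ``branch`` (leaf or internal label)."""

    branch: str
    codon_site: int
    derived_codon: str


@dataclass
class SimSpec:
    """Study conditions for one simulation."""

    tree: str | dendropy.Tree
    n_codons: int
    kappa: float = 2.0
    omega: float | Mapping[str, float] = 0.2
    pi: str | np.ndarray = "uniform"
    seed: int | None = None
    planted_events: Sequence[PlantedEvent] = field(default_factory=tuple)

    def __post_init__(self):
        if self.seed is None:
            raise SimulationError("a seed is mandatory for reproducibility")
        seen = set()
        for p in self.planted_events:
            key = (p.branch, p.codon_site)
            if key in seen:
                raise SimulationError(f"duplicate planted site on branch: {key}")
            seen.add(key)


@dataclass(frozen=True)
class TrueEvent:
    branch: str  # child-node label
    codon_site: int  # 1-based
    from_codon: str
    to_codon: str
    time: float  # position along the branch
    planted: bool = False


@dataclass
class SimTruth:
    """Complete simulated history: per-node sequences and per-branch events."""

    tree: dendropy.Tree
    node_codons: Mapping[str, list]  # label -> list of codon strings
    events: list
    root_label: str

    def events_on(self, branch: str) -> list:
        return [e for e in self.events if e.branch == branch]

    def replay_consistent(self) -> bool:
        """Replaying the events from the root reproduces every node sequence."""
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            child = _label(nd)
            parent = _label(nd.parent_node)
            seq = list(self.node_codons[parent])
            for e in sorted(self.events_on(child), key=lambda e: e.time):
                if seq[e.codon_site - 1] != e.from_codon:
                    return False
                seq[e.codon_site - 1] = e.to_codon
            if seq != self.node_codons[child]:
                return False
        return True


def _label(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label


class _GY94Sampler:
    """Exact per-site stochastic simulation machinery for one (kappa, omega)."""

    def __init__(self, kappa, omega, pi, code):
        Q = build_q(kappa, omega, pi, code)
        self.rates = -np.diag(Q).copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            J = Q / self.rates[:, None]
        J[np.diag_indices_from(J)] = 0.0
        J[~np.isfinite(J)] = 0.0
        self.jump_cdf = np.cumsum(J, axis=1)

    def evolve_site(self, state: int, t: float, rng) -> tuple:
        """Evolve one site for time t; returns (end state, [(time, from, to)])."""
        events = []
        now = 0.0
        while True:
            r = self.rates[state]
            if r <= 0:
                break
            now += rng.exponential(1.0 / r)
            if now >= t:
                break
            u = rng.random()
            new = int(np.searchsorted(self.jump_cdf[state], u * self.jump_cdf[state, -1]))
            events.append((now, state, new))
            state = new
        return state, events


def _prepare_tree(tree) -> dendropy.Tree:
    t = tree.clone(depth=1) if isinstance(tree, dendropy.Tree) else read_newick(tree)
    k = 0
    for nd in t.preorder_node_iter():
        if not nd.is_leaf() and not nd.label:
            nd.label = f"node{k}"
        k += 1
    return t


def simulate_alignment(spec: SimSpec, code: GeneticCode | None = None):
    """Simulate a codon alignment on the spec's tree.

    The root sequence is drawn from pi; every branch evolves by exact
    event-by-event simulation; planted events (if any) are applied via
    :func:`plant_events`.  Returns (CodonAlignment, SimTruth), reproducible
    given the spec's seed.
    """
    code = code or standard_code()
    tree = _prepare_tree(spec.tree)
    n_states = len(code.sense_codons)
    if isinstance(spec.pi, str):
        if spec.pi != "uniform":
            raise SimulationError(f"unknown pi source {spec.pi!r}")
        pi = np.full(n_states, 1.0 / n_states)
    else:
        pi = np.asarray(spec.pi, dtype=float)
    rng = np.random.default_rng(spec.seed)

    samplers = {}

    def sampler_for(branch_label: str) -> _GY94Sampler:
        om = (
            spec.omega[branch_label]
            if isinstance(spec.omega, Mapping)
            else spec.omega
        )
        if om not in samplers:
            samplers[om] = _GY94Sampler(spec.kappa, om, pi, code)
        return samplers[om]

    sense = code.sense_codons
    root_states = rng.choice(n_states, size=spec.n_codons, p=pi)
    node_states = {_label(tree.seed_node): root_states}
    events = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        child = _label(nd)
        t = nd.edge.length or 0.0
        parent_states = node_states[_label(nd.parent_node)]
        sam = sampler_for(child)
        states = parent_states.copy()
        for s in range(spec.n_codons):
            end, evs = sam.evolve_site(int(states[s]), t, rng)
            for time, a, b in evs:
                events.append(
                    TrueEvent(child, s + 1, sense[a], sense[b], time)
                )
            states[s] = end
        node_states[child] = states

    node_codons = {
        lab: [sense[k] for k in st] for lab, st in node_states.items()
    }
    truth = SimTruth(
        tree=tree,
        node_codons=node_codons,
        events=events,
        root_label=_label(tree.seed_node),
    )
    aln = _alignment_from_truth(truth)
    if spec.planted_events:
        aln, truth = plant_events(
            (aln, truth), spec.planted_events, spec=spec, code=code,
            rng=np.random.default_rng(spec.seed + 1_000_003),
        )
    return aln, truth


def _alignment_from_truth(truth: SimTruth) -> CodonAlignment:
    taxa = []
    seqs = []
    for lf in truth.tree.leaf_node_iter():
        lab = _label(lf)
        taxa.append(lab)
        seqs.append("".join(truth.node_codons[lab]))
    return CodonAlignment(taxa, seqs)


def plant_events(
    sim,
    plantings: Sequence[PlantedEvent],
    spec: SimSpec,
    code: GeneticCode | None = None,
    rng: np.random.Generator | None = None,
):
    """Overwrite chosen (branch, site) outcomes with forced derived codons.

    At each planting the child-node state at that site is set to the derived
    codon (recorded as a planted event at the end of the branch) and the
    site is re-simulated downstream from the forced state; SimTruth is
    updated accordingly.  Planting a stop codon, or on a branch whose
    parent state already equals the derived codon at a leaf branch, is
    rejected / a logged no-op as appropriate.
    """
    aln, truth = sim
    code = code or standard_code()
    rng = rng if rng is not None else np.random.default_rng((spec.seed or 0) + 1)
    sense = code.sense_codons
    index = code.codon_index
    nodes = {_label(nd): nd for nd in truth.tree.preorder_node_iter()}

    samplers = {}

    def sampler_for(branch_label: str) -> _GY94Sampler:
        om = (
            spec.omega[branch_label]
            if isinstance(spec.omega, Mapping)
            else spec.omega
        )
        if om not in samplers:
            n = len(sense)
            pi = (
                np.full(n, 1.0 / n)
                if isinstance(spec.pi, str)
                else np.asarray(spec.pi, dtype=float)
            )
            samplers[om] = _GY94Sampler(spec.kappa, om, pi, code)
        return samplers[om]

    for p in plantings:
        if p.derived_codon not in index:
            raise SimulationError(
                f"planted codon {p.derived_codon!r} is not a sense codon"
            )
        if p.branch not in nodes or nodes[p.branch].parent_node is None:
            raise SimulationError(f"no branch above node {p.branch!r}")
        nd = nodes[p.branch]
        parent_codon = truth.node_codons[_label(nd.parent_node)][p.codon_site - 1]
        if parent_codon == p.derived_codon:
            if nd.is_leaf():
                continue  # no-op: the leaf is already in the derived state
            raise SimulationError(
                f"planted codon equals the parent state on branch {p.branch!r}"
            )
        site = p.codon_site
        # wipe the site's recorded history in the subtree (branch included)
        sub_labels = {_label(x) for x in nd.preorder_iter()}
        truth.events = [
            e
            for e in truth.events
            if not (e.codon_site == site and e.branch in sub_labels)
        ]
        truth.events.append(
            TrueEvent(
                p.branch, site, parent_codon, p.derived_codon,
                time=nd.edge.length or 0.0, planted=True,
            )
        )
        truth.node_codons[p.branch][site - 1] = p.derived_codon
        # re-simulate the site below the planted branch
        for desc in nd.preorder_iter():
            if desc is nd:
                continue
            child = _label(desc)
            parent_state = index[truth.node_codons[_label(desc.parent_node)][site - 1]]
            sam = sampler_for(child)
            end, evs = sam.evolve_site(parent_state, desc.edge.length or 0.0, rng)
            for time, a, b in evs:
                truth.events.append(TrueEvent(child, site, sense[a], sense[b], time))
            truth.node_codons[child][site - 1] = sense[end]
    return _alignment_from_truth(truth), truth


# ---------------------------------------------------------------------------
# the bat-like study fixture


#: 1-based codon site <-> bovine-reference numbering offset for the fixture
FIXTURE_OFFSET = 15

_PTERO = [f"pteropodidae_{i}" for i in range(1, 6)]
_RHINO = [f"rhinolophoidea_{i}" for i in range(1, 6)]
_MINIO = [f"miniopterus_{i}" for i in range(1, 4)]
_YANGO = [f"yangochiroptera_{i}" for i in range(1, 10)]
_TOMB = "tombbat_1"

_FIXTURE_NEWICK = (
    "(("
    f"(({_PTERO[0]}:0.015,{_PTERO[1]}:0.015)ptero_a:0.035,"
    f"({_PTERO[2]}:0.015,({_PTERO[3]}:0.015,{_PTERO[4]}:0.015)ptero_c:0.035)ptero_b:0.035)ptero_stem:0.035,"
    f"({_RHINO[0]}:0.015,({_RHINO[1]}:0.015,({_RHINO[2]}:0.015,"
    f"({_RHINO[3]}:0.015,{_RHINO[4]}:0.015)rhino_c:0.035)rhino_b:0.035)rhino_a:0.035)rhino_stem:0.03"
    ")yinpterochiroptera:0.02,"
    "("
    f"{_TOMB}:0.015,"
    f"(({_YANGO[0]}:0.015,({_YANGO[1]}:0.015,{_YANGO[2]}:0.015)yango_a2:0.035)yango_a:0.035,"
    f"((({_MINIO[0]}:0.015,({_MINIO[1]}:0.015,{_MINIO[2]}:0.015)minio_a:0.035)minio_stem:0.035,"
    f"({_YANGO[3]}:0.015,({_YANGO[4]}:0.015,{_YANGO[5]}:0.015)yango_b2:0.035)yango_b:0.035)yango_bm:0.035,"
    f"({_YANGO[6]}:0.015,({_YANGO[7]}:0.015,{_YANGO[8]}:0.015)yango_c2:0.035)yango_c:0.03"
    f")yango_core:0.035)yango_rad:0.03"
    ")yangochiroptera:0.02"
    ")root;"
)

#: planted replacements: reference site -> (ancestral codon, derived codon,
#: branches).  Codon pairs are chosen so every differing nucleotide column
#: falls in a nonsynonymous site class (no leakage of the planted signal
#: into synonymous distances).
FIXTURE_PLANTINGS = {
    270: ("TCT", "GGT", ("ptero_stem", _TOMB)),  # S270G: fruit bats + tomb bat
    104: ("GTA", "ATA", ("minio_stem", "rhino_stem")),  # V104I
    183: ("ATG", "CTG", ("minio_stem", "rhino_stem")),  # M183L
}


def fixture_clades() -> dict:
    return {
        "pteropodidae": list(_PTERO),
        "rhinolophoidea": list(_RHINO),
        "miniopterus": list(_MINIO),
        "yangochiroptera_other": list(_YANGO),
        "tombbat": [_TOMB],
    }


def ref_to_codon_site(reference_site: int, offset: int = FIXTURE_OFFSET) -> int:
    return reference_site - offset


def bat_fixture(seed: int, code: GeneticCode | None = None):
    """The bat-like study fixture.

    Returns (alignment, species tree, config) where config records the
    clade memberships, the site-numbering offset, the planted sites and the
    simulation truth.  23 taxa x 278 codons (834 bp), kappa = 3,
    omega = 0.03.
    """
    code = code or standard_code()
    n_codons = 278
    plantings = []
    forced_root = {}
    for ref, (anc, der, branches) in FIXTURE_PLANTINGS.items():
        site = ref_to_codon_site(ref)
        forced_root[site] = anc
        for b in branches:
            plantings.append(PlantedEvent(b, site, der))
    spec = SimSpec(
        tree=_FIXTURE_NEWICK,
        n_codons=n_codons,
        kappa=3.0,
        omega=0.03,
        pi="uniform",
        seed=seed,
        planted_events=(),
    )
    tree = _prepare_tree(spec.tree)
    # simulate with the ancestral codons forced at the planted sites, then
    # apply the plantings
    aln, truth = _simulate_with_forced_root(spec, tree, forced_root, code)
    aln, truth = plant_events(
        (aln, truth), plantings, spec=spec, code=code,
        rng=np.random.default_rng(seed + 1_000_003),
    )
    config = {
        "offset": FIXTURE_OFFSET,
        "clades": fixture_clades(),
        "planted": {
            ref: {
                "codon_site": ref_to_codon_site(ref),
                "ancestral": anc,
                "derived": der,
                "branches": list(branches),
            }
            for ref, (anc, der, branches) in FIXTURE_PLANTINGS.items()
        },
        "kappa": 3.0,
        "omega": 0.03,
        "seed": seed,
        "truth": truth,
    }
    species_tree = _prepare_tree(_FIXTURE_NEWICK)
    return aln, species_tree, config


def _simulate_with_forced_root(spec, tree, forced_root, code):
    """Simulate like :func:`simulate_alignment` but with chosen root codons
    at given 1-based sites."""
    n_states = len(code.sense_codons)
    pi = np.full(n_states, 1.0 / n_states)
    rng = np.random.default_rng(spec.seed)
    sam = _GY94Sampler(spec.kappa, spec.omega, pi, code)
    sense = code.sense_codons
    root_states = rng.choice(n_states, size=spec.n_codons, p=pi)
    for site, codon in forced_root.items():
        root_states[site - 1] = code.codon_index[codon]
    node_states = {_label(tree.seed_node): root_states}
    events = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        child = _label(nd)
        states = node_states[_label(nd.parent_node)].copy()
        for s in range(spec.n_codons):
            end, evs = sam.evolve_site(int(states[s]), nd.edge.length or 0.0, rng)
            for time, a, b in evs:
                events.append(TrueEvent(child, s + 1, sense[a], sense[b], time))
            states[s] = end
        node_states[child] = states
    node_codons = {lab: [sense[k] for k in st] for lab, st in node_states.items()}
    truth = SimTruth(
        tree=tree, node_codons=node_codons, events=events,
        root_label=_label(tree.seed_node),
    )
    return _alignment_from_truth(truth), truth
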