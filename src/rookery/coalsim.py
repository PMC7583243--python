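"""Structured coalescent simulation with timed demographic events.

Simulates matrilineal (haploid) genealogies in a set of demes connected by
timed split and admixture-pulse events (and, for the island-model test
variant, continuous migration), then drops Kimura-two-parameter mutations on
the genealogy to produce control-region-like alignments.

Scaling is haploid throughout, as appropriate for mtDNA: within a deme of
size N, each pair of lineages coalesces at rate 1/N per generation, so
E[TMRCA] of a pair is N generations and theta = 2 N mu.

Events are described *backward in time*: a ``split`` event at time t moves
every lineage of the derived deme into its source (the derived deme was
founded from the source at t, forward in time); an ``admixture`` event moves
each lineage of the destination deme into the pulse source independently
with the admixture fraction (the destination received that fraction of
immigrants at t, forward in time).

The five built-in colonization scenarios for the Atlantic loggerhead system
are shipped as YAML files; see :func:`builtin_scenarios`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .seqdata import Alignment, decode_matrix

__all__ = [
    "Prior",
    "Deme",
    "Event",
    "ScenarioSpec",
    "ScenarioError",
    "Genealogy",
    "SimulatedDataset",
    "validate_scenario",
    "sample_priors",
    "simulate_genealogy",
    "mutate_k2p",
    "simulate_dataset",
    "builtin_scenarios",
    "scenario_from_yaml",
    "load_scenario",
    "island_pair_scenario",
    "expected_island_fst",
]


class ScenarioError(ValueError):
    """Raised for topologically or numerically inconsistent scenarios."""


# ---------------------------------------------------------------------------
# Scenario description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """A univariate prior: fixed, uniform, uniform_int or loguniform."""
    kind: str
    low: float = 0.0
    high: float = 0.0
    value: float = 0.0

    def __post_init__(self):
        if self.kind not in {"fixed", "uniform", "uniform_int", "loguniform"}:
            raise ScenarioError(f"unknown prior kind {self.kind!r}")
        if self.kind != "fixed" and self.low > self.high:
            raise ScenarioError(f"prior has min > max: {self}")
        if self.kind == "loguniform" and self.low <= 0:
            raise ScenarioError("loguniform prior needs a positive lower bound")

    @classmethod
    def fixed(cls, value: float) -> "Prior":
        return cls("fixed", value=value)

    @classmethod
    def of(cls, spec) -> "Prior":
        """Build from a number (fixed) or a mapping with ``kind``/bounds."""
        if isinstance(spec, Prior):
            return spec
        if isinstance(spec, (int, float)):
            return cls.fixed(float(spec))
        kind = spec["kind"]
        if kind == "fixed":
            return cls.fixed(float(spec["value"]))
        return cls(kind, float(spec["low"]), float(spec["high"]))

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.kind == "uniform_int":
            return float(rng.integers(int(self.low), int(self.high) + 1))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    @property
    def min(self) -> float:
        return self.value if self.kind == "fixed" else self.low

    @property
    def max(self) -> float:
        return self.value if self.kind == "fixed" else self.high

    def to_dict(self):
        if self.kind == "fixed":
            return {"kind": "fixed", "value": self.value}
        return {"kind": self.kind, "low": self.low, "high": self.high}


#: Default effective-size prior for every deme (haploid individuals).
DEFAULT_SIZE_PRIOR = Prior("uniform_int", 100, 500)
#: Default per-site per-generation mutation-rate prior.  The rate is allowed
#: to vary uniformly across [1e-7, 1e-3]; a log-uniform alternative is
#: available because a linear-uniform prior over four orders of magnitude
#: concentrates mass at high rates.
DEFAULT_RATE_PRIOR = Prior("uniform", 1e-7, 1e-3)
#: Standard time windows (generations, backward) used by the built-in
#: colonization scenarios; t1 is calibrated so that, at 50 years per
#: generation, the youngest founding falls 4000-5000 years before present.
TIME_WINDOWS = {
    "t1": (80, 100),
    "t2": (2000, 3999),
    "t3": (4000, 5999),
    "t4": (6000, 8999),
    "t5": (9000, 10000),
}
DEFAULT_GENERATION_TIME = 50.0
DEFAULT_KAPPA = 2.0
DEFAULT_SITES = 674


@dataclass(frozen=True)
class Deme:
    name: str
    size: Prior = DEFAULT_SIZE_PRIOR
    samples: int = 0


@dataclass(frozen=True)
class Event:
    """A timed demographic event (backward-time semantics, see module doc)."""
    kind: str                      # split | admixture | size_change
    deme: str                      # derived deme / pulse destination
    time: Prior
    source: str | None = None
    fraction: Prior | None = None  # admixture only
    new_size: Prior | None = None  # size_change only

    def __post_init__(self):
        if self.kind not in {"split", "admixture", "size_change"}:
            raise ScenarioError(f"unknown event kind {self.kind!r}")


@dataclass
class ScenarioSpec:
    """A demographic scenario: demes, events, mutation model and clock."""
    name: str
    demes: list[Deme]
    events: list[Event]
    mutation_rate: Prior = DEFAULT_RATE_PRIOR
    kappa: float = DEFAULT_KAPPA
    sites: int = DEFAULT_SITES
    generation_time_years: float = DEFAULT_GENERATION_TIME
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    description: str = ""

    @property
    def deme_names(self) -> list[str]:
        return [d.name for d in self.demes]

    @property
    def sampled_demes(self) -> list[str]:
        return [d.name for d in self.demes if d.samples > 0]

    @property
    def n_samples(self) -> int:
        return sum(d.samples for d in self.demes)

    def with_samples(self, samples: dict[str, int]) -> "ScenarioSpec":
        """A copy with per-deme sample sizes replaced (unlisted demes -> 0)."""
        demes = [replace(d, samples=int(samples.get(d.name, 0)))
                 for d in self.demes]
        return replace(self, demes=demes)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_scenario(s: ScenarioSpec) -> ScenarioSpec:
    """Check topological consistency; raises :class:`ScenarioError` naming
    the offending deme or event."""
    names = s.deme_names
    if len(set(names)) != len(names):
        raise ScenarioError("duplicate deme names")
    for ev in s.events:
        if ev.deme not in names:
            raise ScenarioError(f"event references unknown deme {ev.deme!r}: {ev}")
        if ev.kind in {"split", "admixture"}:
            if ev.source not in names:
                raise ScenarioError(f"event references unknown source: {ev}")
            if ev.source == ev.deme:
                raise ScenarioError(f"event with source == deme: {ev}")
        if ev.time.min <= 0:
            raise ScenarioError(f"event at time <= 0: {ev}")
        if ev.kind == "admixture":
            if ev.fraction is None:
                raise ScenarioError(f"admixture without fraction: {ev}")
            if not (0.0 < ev.fraction.min and ev.fraction.max < 1.0):
                raise ScenarioError(
                    f"admixture fraction outside (0, 1): {ev}")
        if ev.kind == "size_change" and ev.new_size is None:
            raise ScenarioError(f"size_change without new_size: {ev}")
    for d in s.demes:
        if d.samples < 0:
            raise ScenarioError(f"negative sample size for deme {d.name}")
        if d.size.min <= 0:
            raise ScenarioError(f"non-positive size prior for deme {d.name}")
    splits = [ev for ev in s.events if ev.kind == "split"]
    closed = [ev.deme for ev in splits]
    if len(set(closed)) != len(closed):
        raise ScenarioError("a deme is the derived side of more than one split")
    for a, b in s.migration:
        if a not in names or b not in names:
            raise ScenarioError(f"migration between unknown demes {(a, b)}")
    if not s.migration:
        roots = [n for n in names if n not in closed]
        if len(roots) != 1:
            raise ScenarioError(
                f"expected exactly one root deme, found {roots!r} "
                "(orphan demes must be closed by a split)")
        # cyclic-ancestry check: walk split chains
        close_of = {ev.deme: ev for ev in splits}
        for n in names:
            seen = set()
            cur = n
            while cur in close_of:
                if cur in seen:
                    raise ScenarioError(f"cyclic ancestry through deme {cur!r}")
                seen.add(cur)
                cur = close_of[cur].source
            if cur != roots[0]:
                raise ScenarioError(
                    f"deme {n!r} does not trace to the root deme")
        # times along an ancestry chain must be orderable
        for ev in close_of.values():
            src = ev.source
            if src in close_of and close_of[src].time.max <= ev.time.min:
                raise ScenarioError(
                    f"deme {src!r} closes before its derived deme {ev.deme!r}")
    # listed events must admit strictly increasing realized times
    for e1, e2 in zip(s.events, s.events[1:]):
        if e1.time.min >= e2.time.max:
            raise ScenarioError(
                f"events cannot be ordered in listed order: {e1} !< {e2}")
    return s


# ---------------------------------------------------------------------------
# Prior sampling
# ---------------------------------------------------------------------------

def sample_priors(s: ScenarioSpec, seed: int | np.random.Generator):
    """One concrete parameter draw from the scenario's priors.

    Event times are drawn independently from their windows and the whole
    vector is rejected and redrawn until the realized times are strictly
    increasing in listed order (windows of the built-in scenarios are
    disjoint, so rejection is rare).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sizes = {d.name: max(1.0, s.demes[i].size.sample(rng))
             for i, d in enumerate(s.demes)}
    for _ in range(10_000):
        times = [ev.time.sample(rng) for ev in s.events]
        if all(t1 < t2 for t1, t2 in zip(times, times[1:])):
            break
    else:
        raise ScenarioError("could not draw strictly ordered event times")
    fractions = [ev.fraction.sample(rng) if ev.fraction is not None else None
                 for ev in s.events]
    new_sizes = [ev.new_size.sample(rng) if ev.new_size is not None else None
                 for ev in s.events]
    return {
        "sizes": sizes,
        "times": times,
        "fractions": fractions,
        "new_sizes": new_sizes,
        "mu": s.mutation_rate.sample(rng),
    }


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A coalescent tree over ``n_samples`` tips (nodes 0..n-1 at time 0).

    ``parent[i]`` is the parent node of i (-1 for the root); ``time[i]`` the
    node age in generations.  ``sample_demes`` gives the deme of each tip.
    """
    n_samples: int
    parent: np.ndarray
    time: np.ndarray
    sample_demes: list[str]

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    @property
    def total_length(self) -> float:
        root = int(np.argmax(self.time))
        lengths = self.time[self.parent] - self.time
        lengths[root] = 0.0
        return float(lengths.sum())


def simulate_genealogy(s: ScenarioSpec, draw: dict,
                       seed: int | np.random.Generator) -> Genealogy:
    """Continuous-time structured coalescent under a concrete draw.

    Within a deme of haploid size N each lineage pair coalesces at rate 1/N
    per generation; timed events move lineages between demes as described in
    the module docstring; optional continuous migration moves single
    lineages at their per-generation rates (island-model variant).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sizes = dict(draw["sizes"])
    n_tot = s.n_samples
    if n_tot < 2:
        raise ScenarioError("need at least two sampled lineages")
    max_nodes = 2 * n_tot - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    time = np.zeros(max_nodes)
    sample_demes: list[str] = []
    active: dict[str, list[int]] = {d.name: [] for d in s.demes}
    nid = 0
    for d in s.demes:
        for _ in range(d.samples):
            active[d.name].append(nid)
            sample_demes.append(d.name)
            nid += 1
    events = sorted(zip(s.events, draw["times"], draw["fractions"],
                        draw["new_sizes"]), key=lambda e: e[1])
    mig = [(a, b, m) for (a, b), m in s.migration.items() if m > 0]
    t = 0.0
    ev_i = 0
    n_active = n_tot
    while n_active > 1:
        coal_rates = []
        for name, lin in active.items():
            k = len(lin)
            if k >= 2:
                coal_rates.append((name, k * (k - 1) / (2.0 * sizes[name])))
        mig_rates = [(a, b, len(active[a]) * m) for a, b, m in mig
                     if active[a]]
        total = sum(r for _, r in coal_rates) + sum(r for *_, r in mig_rates)
        if total == 0.0:
            if ev_i >= len(events):
                stuck = {k: len(v) for k, v in active.items() if v}
                raise ScenarioError(
                    f"lineages cannot coalesce (stranded in {stuck}) — "
                    "scenario does not merge all demes")
            t_next = events[ev_i][1]
        else:
            t_next = t + rng.exponential(1.0 / total)
        if ev_i < len(events) and events[ev_i][1] <= t_next:
            ev, ev_t, frac, nsz = events[ev_i]
            t = ev_t
            ev_i += 1
            if ev.kind == "split":
                active[ev.source].extend(active[ev.deme])
                active[ev.deme] = []
            elif ev.kind == "admixture":
                stay = []
                for node in active[ev.deme]:
                    if rng.random() < frac:
                        active[ev.source].append(node)
                    else:
                        stay.append(node)
                active[ev.deme] = stay
            else:  # size_change
                sizes[ev.deme] = max(1.0, nsz)
            continue
        t = t_next
        u = rng.random() * total
        acc = 0.0
        chosen = None
        for name, r in coal_rates:
            acc += r
            if u < acc:
                chosen = ("coal", name)
                break
        if chosen is None:
            for a, b, r in mig_rates:
                acc += r
                if u < acc:
                    chosen = ("mig", a, b)
                    break
        if chosen is None:  # numerical edge: take the last category
            chosen = ("coal", coal_rates[-1][0]) if coal_rates else \
                ("mig", mig_rates[-1][0], mig_rates[-1][1])
        if chosen[0] == "coal":
            lin = active[chosen[1]]
            k = len(lin)
            i = rng.integers(0, k)
            j = rng.integers(0, k - 1)
            if j >= i:
                j += 1
            c1, c2 = lin[i], lin[j]
            parent[c1] = nid
            parent[c2] = nid
            time[nid] = t
            lin[min(i, j)] = nid
            lin.pop(max(i, j))
            nid += 1
            n_active -= 1
        else:
            _, a, b = chosen
            lin = active[a]
            i = rng.integers(0, len(lin))
            active[b].append(lin.pop(i))
    return Genealogy(n_tot, parent[:nid], time[:nid], sample_demes)


# ---------------------------------------------------------------------------
# K2P mutation
# ---------------------------------------------------------------------------

def _k2p_probs(rate: float, kappa: float, t: float):
    """(P_transition, P_each_transversion) for a branch of t generations at
    per-site rate *rate* with transition/transversion ratio *kappa*."""
    alpha = rate * kappa / (kappa + 2.0)
    beta = rate / (kappa + 2.0)
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return max(p_ts, 0.0), max(p_tv, 0.0)


def mutate_k2p(gen: Genealogy, rate: float, kappa: float, sites: int,
               seed: int | np.random.Generator,
               root_seq: np.ndarray | None = None) -> np.ndarray:
    """Evolve sequences down the genealogy under Kimura-2-parameter.

    The substitution process on each branch is the exact K2P continuous-time
    Markov chain (Poisson mutation events with transition:transversion odds
    kappa:2, composed over the branch), sampled per site from the closed-form
    transition matrix.  The root sequence is uniform over the four bases
    unless supplied.  Returns the (n_samples, sites) uint8 matrix of tip
    sequences in the 0..3 encoding of :mod:`rookery.seqdata`.
    """
    if rate < 0:
        raise ValueError("mutation rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_nodes = len(gen.parent)
    root = int(np.argmax(gen.time))
    seqs = np.empty((n_nodes, sites), dtype=np.uint8)
    if root_seq is None:
        seqs[root] = rng.integers(0, 4, size=sites, dtype=np.uint8)
    else:
        seqs[root] = np.asarray(root_seq, dtype=np.uint8)
    # Per-branch change codes are XOR masks independent of the parent state
    # (transition partner is x^1, transversion partners x^2 / x^3), so they
    # can be drawn for all branches in one vectorised block and composed
    # down the tree with one XOR per node.
    dts = np.where(np.arange(n_nodes) == root, 0.0,
                   gen.time[gen.parent] - gen.time)
    if rate > 0:
        alpha = rate * kappa / (kappa + 2.0)
        beta = rate / (kappa + 2.0)
        e1 = np.exp(-4.0 * beta * dts)
        e2 = np.exp(-2.0 * (alpha + beta) * dts)
        p_ts = np.maximum(0.25 + 0.25 * e1 - 0.5 * e2, 0.0)[:, None]
        p_tv = np.maximum(0.25 - 0.25 * e1, 0.0)[:, None]
        u = rng.random((n_nodes, sites))
        delta = np.zeros((n_nodes, sites), dtype=np.uint8)
        delta[u < p_ts] = 1
        delta[(u >= p_ts) & (u < p_ts + p_tv)] = 2
        delta[(u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)] = 3
    else:
        delta = np.zeros((n_nodes, sites), dtype=np.uint8)
    order = np.argsort(gen.time)[::-1]
    for node in order:
        if node == root:
            continue
        seqs[node] = seqs[gen.parent[node]] ^ delta[node]
    return seqs[: gen.n_samples]


# ---------------------------------------------------------------------------
# End-to-end dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """One simulated dataset: tip sequences, the realized parameter draw and
    genealogy summaries."""
    matrix: np.ndarray
    sample_demes: list[str]
    params: dict
    tmrca: float
    total_length: float
    scenario: str = ""

    def to_alignment(self, prefix: str = "sim") -> Alignment:
        import pandas as pd
        ids = [f"{prefix}{i:05d}" for i in range(self.matrix.shape[0])]
        labels = pd.DataFrame({"level1": self.sample_demes,
                               "level2": pd.NA, "level3": pd.NA}, index=ids)
        a = Alignment(ids, decode_matrix(self.matrix), labels)
        a.unit_order = {1: list(dict.fromkeys(self.sample_demes))}
        return a


def simulate_dataset(s: ScenarioSpec, seed: int | np.random.Generator,
                     draw: dict | None = None) -> SimulatedDataset:
    """sample_priors -> simulate_genealogy -> mutate_k2p, deterministic under
    the seed."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if draw is None:
        draw = sample_priors(s, rng)
    gen = simulate_genealogy(s, draw, rng)
    mat = mutate_k2p(gen, draw["mu"], s.kappa, s.sites, rng)
    return SimulatedDataset(mat, gen.sample_demes, draw, gen.tmrca,
                            gen.total_length, s.name)


# ---------------------------------------------------------------------------
# Built-in scenarios and YAML I/O
# ---------------------------------------------------------------------------

def scenario_from_yaml(text: str) -> ScenarioSpec:
    doc = yaml.safe_load(text)
    if doc.get("format") != "rookery-scenario-v1":
        raise ScenarioError("not a rookery-scenario-v1 document")
    demes = [Deme(d["name"], Prior.of(d.get("size", DEFAULT_SIZE_PRIOR)),
                  int(d.get("samples", 0))) for d in doc["demes"]]
    events = []
    for e in doc.get("events", []):
        events.append(Event(
            kind=e["kind"], deme=e["deme"], time=Prior.of(e["time"]),
            source=e.get("source"),
            fraction=Prior.of(e["fraction"]) if "fraction" in e else None,
            new_size=Prior.of(e["new_size"]) if "new_size" in e else None))
    migration = {}
    for m in doc.get("migration", []):
        migration[(m["from"], m["to"])] = float(m["rate"])
    spec = ScenarioSpec(
        name=doc["name"], demes=demes, events=events,
        mutation_rate=Prior.of(doc.get("mutation_rate", DEFAULT_RATE_PRIOR)),
        kappa=float(doc.get("kappa", DEFAULT_KAPPA)),
        sites=int(doc.get("sites", DEFAULT_SITES)),
        generation_time_years=float(doc.get("generation_time_years",
                                            DEFAULT_GENERATION_TIME)),
        migration=migration,
        description=doc.get("description", ""))
    return validate_scenario(spec)


def scenario_to_yaml(s: ScenarioSpec) -> str:
    doc = {
        "format": "rookery-scenario-v1",
        "name": s.name,
        "description": s.description,
        "sites": s.sites,
        "generation_time_years": s.generation_time_years,
        "kappa": s.kappa,
        "mutation_rate": s.mutation_rate.to_dict(),
        "demes": [{"name": d.name, "size": d.size.to_dict(),
                   "samples": d.samples} for d in s.demes],
        "events": [],
    }
    for e in s.events:
        ed = {"kind": e.kind, "deme": e.deme, "time": e.time.to_dict()}
        if e.source:
            ed["source"] = e.source
        if e.fraction is not None:
            ed["fraction"] = e.fraction.to_dict()
        if e.new_size is not None:
            ed["new_size"] = e.new_size.to_dict()
        doc["events"].append(ed)
    if s.migration:
        doc["migration"] = [{"from": a, "to": b, "rate": m}
                            for (a, b), m in s.migration.items()]
    return yaml.safe_dump(doc, sort_keys=False)


def load_scenario(path: str | Path) -> ScenarioSpec:
    return scenario_from_yaml(Path(path).read_text())


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """The five built-in Atlantic colonization scenarios S1..S5.

    S5 encodes the two-wave history in which Brazil is the most ancient
    rookery (founded by the haplogroup-I ancestor), which then colonized
    Cabo Verde and from there USA/Mexico, while the Mediterranean was founded
    last and only by haplogroup II, whose individuals subsequently dispersed
    to USA/Mexico and from there to Cabo Verde (admixture pulses).  S1-S4 are
    alternative orderings reconstructed from the competing hypotheses (USA
    ancestral; a USA-ancestral stepping-stone through Cabo Verde; a
    Brazil-ancestral single wave; and a two-wave history without return
    dispersal); their event-level details are this package's reconstruction.
    """
    out = {}
    for i in range(1, 6):
        text = (resources.files("rookery.scenarios")
                .joinpath(f"s{i}.yaml").read_text())
        spec = scenario_from_yaml(text)
        out[spec.name] = spec
    return out


# ---------------------------------------------------------------------------
# Island-model variant (testing oracle)
# ---------------------------------------------------------------------------

def island_pair_scenario(n_haploid: int, scaled_migrants: float,
                         samples: int, sites: int = DEFAULT_SITES,
                         mutation_rate: float = 1e-5,
                         kappa: float = DEFAULT_KAPPA) -> ScenarioSpec:
    """Two demes of haploid size N exchanging migrants at equilibrium.

    ``scaled_migrants`` is M = Nm, the total number of lineages exchanged
    between the two demes per generation, both directions combined; each
    lineage therefore migrates at rate M / (2N).  With that convention the
    expected equilibrium fixation index is exactly ``1 / (1 + 2 M)``
    (haploid two-deme coalescent; see :func:`expected_island_fst`).
    """
    rate = scaled_migrants / (2.0 * n_haploid)
    demes = [Deme("demeA", Prior.fixed(n_haploid), samples),
             Deme("demeB", Prior.fixed(n_haploid), samples)]
    return ScenarioSpec(
        name=f"island2_N{n_haploid}_M{scaled_migrants}",
        demes=demes, events=[],
        mutation_rate=Prior.fixed(mutation_rate), kappa=kappa, sites=sites,
        migration={("demeA", "demeB"): rate, ("demeB", "demeA"): rate},
        description="symmetric two-deme island model (testing variant)")


def expected_island_fst(scaled_migrants: float) -> float:
    """Equilibrium F_ST = 1/(1 + 2 M) for the two-deme haploid island model
    parameterised as in :func:`island_pair_scenario`."""
    return 1.0 / (1.0 + 2.0 * scaled_migrants)
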