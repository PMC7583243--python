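"""Study-shaped synthetic data.

Generates alignments that mimic the salient features of a philopatric mtDNA
rookery system without redistributing any real sequences: two deeply
divergent haplogroups (founders separated by a fixed number of point
mutations, 34 by default), star-like within-haplogroup haplotype scatter
with 1-2 dominant haplotypes per unit (Dirichlet frequency skew), a nested
island/beach hierarchy with weak among-unit structure, one island where the
second haplogroup is frequent (driving the largest pairwise F_ST values) and
one isolated beach with perturbed haplotype frequencies (weak but detectable
local structure).

Also houses the small deterministic toy inputs used as oracle targets by the
test suite and the worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import Alignment, decode_matrix, encode_sequences

__all__ = [
    "FixtureConfig",
    "make_haplogroup_founders",
    "generate_study_like_dataset",
    "write_fixture",
    "make_toy_tables",
]

#: Rough island coordinates (lon, lat) for an East-West archipelago layout.
ISLAND_COORDS = {
    "BoaVista": (-22.80, 16.10),
    "Sal": (-22.93, 16.73),
    "Maio": (-23.17, 15.22),
    "Fogo": (-24.36, 14.93),
    "SantoAntao": (-25.09, 17.07),
    "SaoVicente": (-24.98, 16.83),
}
BEACH_COORDS = {
    "BoaEsperanca": (-22.92, 16.16),
    "Lacacao": (-22.72, 15.98),
    "PontaPesqueira": (-22.77, 16.22),
}


@dataclass
class FixtureConfig:
    """Configuration of the study-shaped generator.

    Defaults are deliberately modest in total size (~600 sequences over six
    islands, three beaches on the largest island) so the full battery of
    statistics runs in seconds, while keeping the qualitative features that
    matter: haplogroup divergence of 34 point mutations, skewed haplotype
    frequencies, one island dominated by the second haplogroup and one
    perturbed beach.
    """
    length: int = 780
    divergence: int = 34
    islands: dict[str, int] = field(default_factory=lambda: {
        "BoaVista": 180, "Sal": 100, "Maio": 100, "SaoVicente": 65,
        "Fogo": 60, "SantoAntao": 60})
    #: proportion of haplogroup-II lineages per island
    hg2_mixture: dict[str, float] = field(default_factory=lambda: {
        "BoaVista": 0.02, "Sal": 0.02, "Maio": 0.02, "SaoVicente": 0.70,
        "Fogo": 0.02, "SantoAntao": 0.02})
    #: beaches of the first (largest) island; sizes must sum to its size
    beaches: dict[str, int] = field(default_factory=lambda: {
        "BoaEsperanca": 70, "Lacacao": 55, "PontaPesqueira": 55})
    perturbed_beach: str = "BoaEsperanca"
    haplotypes_per_group: int = 8
    #: Dirichlet concentration < 1 produces the 1-2 dominant haplotypes
    dirichlet_alpha: float = 0.2
    #: how tightly island frequencies track the archipelago-wide frequencies
    unit_concentration: float = 60.0
    perturbed_concentration: float = 4.0
    scatter_mutations: float = 1.5
    rookery_name: str = "CaboVerde"

    def validate(self) -> "FixtureConfig":
        if self.divergence < 0 or self.divergence > self.length:
            raise ValueError("divergence must lie in [0, length]")
        if any(n < 2 for n in self.islands.values()):
            raise ValueError("island sample sizes must be >= 2")
        if not all(0.0 <= f <= 1.0 for f in self.hg2_mixture.values()):
            raise ValueError("mixture proportions must lie in [0, 1]")
        first = next(iter(self.islands))
        if self.beaches and sum(self.beaches.values()) != self.islands[first]:
            raise ValueError(
                f"beach sizes must sum to the size of island {first!r}")
        return self


def make_haplogroup_founders(cfg: FixtureConfig | None = None,
                             seed: int = 0):
    """The two haplogroup founder sequences.

    Founder A is uniform random over the four bases; founder B equals A with
    exactly ``cfg.divergence`` substitutions at distinct uniformly chosen
    sites (34 by default, the divergence separating the two major
    haplogroups).  Returns two uint8 arrays in the 0..3 encoding.
    """
    cfg = (cfg or FixtureConfig()).validate()
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=cfg.length, dtype=np.uint8)
    b = a.copy()
    sites = rng.choice(cfg.length, size=cfg.divergence, replace=False)
    # shift each chosen site by 1..3 states: always a real substitution
    b[sites] = (b[sites] + rng.integers(1, 4, size=cfg.divergence)) % 4
    return a, b


def _haplotype_pool(founder: np.ndarray, k: int, scatter: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Star-like scatter: haplotype 0 is the founder; each other haplotype
    carries 1 + Poisson(scatter) private substitutions."""
    length = len(founder)
    pool = np.tile(founder, (k, 1))
    for h in range(1, k):
        n_mut = 1 + rng.poisson(scatter)
        sites = rng.choice(length, size=min(n_mut, length), replace=False)
        pool[h, sites] = (pool[h, sites] + rng.integers(1, 4, size=len(sites))) % 4
    return pool


def generate_study_like_dataset(cfg: FixtureConfig | None = None,
                                seed: int = 0) -> Alignment:
    """Generate the default study-shaped alignment with its population map.

    Per island, haplotypes are drawn from a two-haplogroup mixture; within a
    haplogroup the archipelago shares a haplotype pool whose global
    frequencies are skewed (Dirichlet with concentration < 1) and island
    frequencies are re-drawn around the global ones (Dirichlet concentration
    ``unit_concentration``), giving weak but non-zero among-island structure.
    The designated beach of the first island gets a much looser concentration,
    emulating a genetically isolated beach.
    """
    cfg = (cfg or FixtureConfig()).validate()
    rng = np.random.default_rng(seed)
    f1, f2 = make_haplogroup_founders(cfg, seed)
    pools = [_haplotype_pool(f, cfg.haplotypes_per_group,
                             cfg.scatter_mutations, rng)
             for f in (f1, f2)]
    k = cfg.haplotypes_per_group
    global_freq = [rng.dirichlet(np.full(k, cfg.dirichlet_alpha))
                   for _ in range(2)]
    ids, seq_rows, rows = [], [], []
    first_island = next(iter(cfg.islands))
    coords = dict(ISLAND_COORDS)
    coords.update(BEACH_COORDS)
    counter = 0
    for island, n in cfg.islands.items():
        mix = cfg.hg2_mixture.get(island, 0.0)
        island_freq = []
        for g in range(2):
            conc = cfg.unit_concentration
            island_freq.append(rng.dirichlet(global_freq[g] * conc + 1e-3))
        if island == first_island and cfg.beaches:
            assignments = [(b, nb) for b, nb in cfg.beaches.items()]
        else:
            assignments = [(None, n)]
        for beach, nb in assignments:
            if beach == cfg.perturbed_beach:
                freqs = [rng.dirichlet(global_freq[g]
                                       * cfg.perturbed_concentration + 1e-3)
                         for g in range(2)]
            else:
                freqs = island_freq
            for _ in range(nb):
                g = 1 if rng.random() < mix else 0
                h = rng.choice(k, p=freqs[g])
                seq_rows.append(pools[g][h])
                counter += 1
                ids.append(f"seq{counter:05d}")
                rows.append({"id": ids[-1], "level1": cfg.rookery_name,
                             "level2": island,
                             "level3": beach if beach else pd.NA})
    mat = np.stack(seq_rows)
    labels = pd.DataFrame(rows).set_index("id")
    aln = Alignment(ids, decode_matrix(mat), labels)
    aln.unit_order = {
        1: [cfg.rookery_name],
        2: list(cfg.islands),
        3: list(cfg.beaches),
    }
    aln.unit_coords = {u: c for u, c in coords.items()
                       if u in cfg.islands or u in cfg.beaches}
    return aln


def write_fixture(aln: Alignment, fasta_path, map_path) -> None:
    """Write a generated fixture as the FASTA + TSV map pair the readers
    consume (round-trips through :mod:`rookery.seqdata`)."""
    from .seqdata import write_fasta, write_population_map
    write_fasta(aln, fasta_path)
    write_population_map(aln, map_path)


# ---------------------------------------------------------------------------
# Deterministic toy inputs (oracle targets)
# ---------------------------------------------------------------------------

def make_toy_tables() -> dict:
    """Small deterministic worked-example inputs.

    Keys:

    - ``hd_counts``: haplotype count vector (5, 3, 2).
    - ``pi_seqs``: four 10-bp sequences for brute-force pairwise checks.
    - ``tajima_alignment``: a fixed 10 x 20 alignment (seeded once).
    - ``contingency_2x2``: the maximally differentiated (10,0 / 0,10) table.
    - ``contingency_small``: a 3-haplotype x 2-unit table enumerable
      exhaustively.
    - ``mantel_d1``/``mantel_d2``: 5 x 5 symmetric matrices.
    - ``eni_rows``: a 6-row directed theta/M table for the regression toy.
    - ``mismatch_uniform2``: the flat two-class histogram (0.5, 0.5).
    """
    rng = np.random.default_rng(20_101_22)
    tajima = rng.integers(0, 4, size=(10, 20), dtype=np.uint8)
    # make a fraction of sites invariant so S < sites
    tajima[:, ::2] = tajima[0, ::2]
    d1 = np.array([[0, 2, 4, 6, 8],
                   [2, 0, 2, 4, 6],
                   [4, 2, 0, 2, 4],
                   [6, 4, 2, 0, 2],
                   [8, 6, 4, 2, 0]], dtype=float)
    rng2 = np.random.default_rng(7)
    noise = rng2.normal(0, 1.0, size=(5, 5))
    d2 = d1 + (noise + noise.T) / 2.0
    np.fill_diagonal(d2, 0.0)
    eni_rows = pd.DataFrame({
        "from": ["A", "A", "B", "B", "C", "C"],
        "to":   ["B", "C", "A", "C", "A", "B"],
        "theta_from": [4.0, 4.0, 6.0, 6.0, 2.0, 2.0],
        "theta_to":   [6.0, 2.0, 4.0, 2.0, 4.0, 6.0],
        "M": [50.0, 20.0, 80.0, 10.0, 40.0, 30.0],
        "run_id": [1] * 6,
    })
    return {
        "hd_counts": np.array([5, 3, 2]),
        "pi_seqs": ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "AAAAAAATTT"],
        "tajima_alignment": tajima,
        "contingency_2x2": np.array([[10, 0], [0, 10]]),
        "contingency_small": np.array([[6, 2], [3, 5], [1, 4]]),
        "mantel_d1": d1,
        "mantel_d2": d2,
        "eni_rows": eni_rows,
        "mismatch_uniform2": np.array([0.5, 0.5]),
    }
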