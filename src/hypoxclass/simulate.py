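"""Negative-binomial scRNA-seq simulator with planted hypoxia states.

The generator emulates the structure the labeling pipeline targets: a
cohort of cells in three ground-truth states — hypoxic, intermediate and
normoxic — in which a panel of hypoxia gene sets is coordinately
upregulated.  Gene baseline rates p_g come from a log-normal and are
normalized to sum to one; cell library sizes L_i are log-normal; the
expected count is

    mu_ig = L_i * p_g * theta^(e_i * m_g)

with m_g = 1 for hypoxia-set genes and e_i = 1 for hypoxic cells,
``intermediate_mixing`` for intermediate cells and 0 for normoxic cells.
Counts are negative-binomial with variance mu + phi * mu^2.  Mitochondrial
genes carry baseline rates only (never part of a hypoxia set), and a
configurable fraction of non-set genes is marked non-protein-coding.

Defaults describe a desk-scale cohort: 2000 cells, 2000 genes, 7 disjoint
sets of 50 genes, 10% hypoxic / 20% intermediate cells, effect multiplier
4 and dispersion 0.3 — overdispersion and sparsity in the range of
droplet scRNA-seq data, without batch effects, doublets or correlation
structure beyond the planted program.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .formats_io import CountMatrix, GeneAnnotation, GeneSetCollection

__all__ = ["SimParams", "SimTruth", "simulate"]

HYPOXIC = "HYPOXIC"
INTERMEDIATE = "INTERMEDIATE"
NORMOXIC = "NORMOXIC"


@dataclass
class SimParams:
    n_cells: int = 2000
    n_genes: int = 2000
    n_sets: int = 7
    set_size: int = 50
    frac_hypoxic: float = 0.10
    frac_intermediate: float = 0.20
    effect_multiplier: float = 4.0      # theta
    intermediate_mixing: float = 0.5
    lib_size_log_mean: float = float(np.log(1e4))
    lib_size_log_sd: float = 0.3
    dispersion: float = 0.3             # phi; variance mu + phi mu^2
    frac_mito_genes: float = 0.02
    frac_noncoding_genes: float = 0.10
    overlap: bool = False
    overlap_core: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_hypoxic + self.frac_intermediate > 1.0:
            raise ValidationError("frac_hypoxic + frac_intermediate must be <= 1")
        if self.effect_multiplier < 1.0:
            raise ValidationError("effect_multiplier must be >= 1")
        if not 0.0 < self.intermediate_mixing < 1.0:
            raise ValidationError("intermediate_mixing must lie in (0, 1)")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        needed = self.set_size * self.n_sets if not self.overlap else (
            self.overlap_core + self.n_sets * (self.set_size - self.overlap_core)
        )
        if needed > self.n_genes:
            raise ValidationError("gene sets do not fit into n_genes")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    states: np.ndarray                      # per-cell HYPOXIC/INTERMEDIATE/NORMOXIC
    effects: np.ndarray                     # realized per-cell exponent e_i
    set_gene_mask: np.ndarray               # bool, genes in any hypoxia set
    table: pd.DataFrame = field(repr=False, default=None)

    def counts(self) -> dict[str, int]:
        return {s: int((self.states == s).sum()) for s in (HYPOXIC, INTERMEDIATE, NORMOXIC)}


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, variance mu + phi mu^2) via gamma-Poisson mixing."""
    shape = 1.0 / phi
    lam = rng.gamma(shape=shape, scale=mu * phi)
    return rng.poisson(lam)


def simulate(params: SimParams) -> tuple[CountMatrix, SimTruth, GeneSetCollection, GeneAnnotation]:
    """Draw one synthetic cohort; same seed gives identical output."""
    rng = np.random.default_rng(params.seed)
    n_c, n_g = params.n_cells, params.n_genes

    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    cell_ids = [f"C{i:05d}" for i in range(n_c)]

    # hypoxia program membership
    sets: dict[str, list[str]] = {}
    member = np.zeros(n_g, dtype=bool)
    if params.overlap:
        core = list(range(params.overlap_core))
        nxt = params.overlap_core
        for s in range(params.n_sets):
            own = list(range(nxt, nxt + params.set_size - params.overlap_core))
            nxt += params.set_size - params.overlap_core
            idx = core + own
            sets[f"HYPOXIA_SET_{s + 1}"] = [gene_ids[i] for i in idx]
            member[idx] = True
    else:
        for s in range(params.n_sets):
            idx = list(range(s * params.set_size, (s + 1) * params.set_size))
            sets[f"HYPOXIA_SET_{s + 1}"] = [gene_ids[i] for i in idx]
            member[idx] = True

    # mito + non-coding genes drawn from outside the program
    non_member = np.flatnonzero(~member)
    n_mito = int(round(params.frac_mito_genes * n_g))
    mito_idx = rng.choice(non_member, size=min(n_mito, non_member.size), replace=False)
    is_mito = np.zeros(n_g, dtype=bool)
    is_mito[mito_idx] = True
    remaining = np.setdiff1d(non_member, mito_idx)
    n_nc = int(round(params.frac_noncoding_genes * n_g))
    nc_idx = rng.choice(remaining, size=min(n_nc, remaining.size), replace=False)
    is_coding = np.ones(n_g, dtype=bool)
    is_coding[nc_idx] = False

    # cell states in fixed blocks, then shuffled
    n_h = int(round(params.frac_hypoxic * n_c))
    n_i = int(round(params.frac_intermediate * n_c))
    states = np.array([HYPOXIC] * n_h + [INTERMEDIATE] * n_i + [NORMOXIC] * (n_c - n_h - n_i),
                      dtype=object)
    rng.shuffle(states)
    effects = np.where(states == HYPOXIC, 1.0,
                       np.where(states == INTERMEDIATE, params.intermediate_mixing, 0.0))

    # rates and counts
    p = rng.lognormal(mean=0.0, sigma=1.0, size=n_g)
    p /= p.sum()
    lib = rng.lognormal(mean=params.lib_size_log_mean, sigma=params.lib_size_log_sd, size=n_c)
    theta_pow = params.effect_multiplier ** (effects[:, None] * member[None, :].astype(float))
    mu = lib[:, None] * p[None, :] * theta_pow
    counts = _nb_sample(rng, mu, params.dispersion)

    cm = CountMatrix(cell_ids, gene_ids, sp.csr_matrix(counts), dataset_tag="synthetic")
    collection = GeneSetCollection(sets, {k: "synthetic hypoxia program" for k in sets})
    ann = GeneAnnotation(pd.DataFrame(
        {"is_protein_coding": is_coding, "is_mitochondrial": is_mito},
        index=pd.Index(gene_ids, name="gene_id"),
    ))
    truth_table = pd.DataFrame({"cell_id": cell_ids, "true_state": states, "effect": effects})
    truth = SimTruth(states, effects, member, truth_table)
    return cm, truth, collection, ann
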