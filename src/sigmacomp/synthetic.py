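"""Synthetic RNA-seq-like count experiments with planted regulon structure.

Emulates the strain x growth-phase design of the real experiment — five
strains (wild-type, Rsd knockout, 6S RNA knockout, double knockout, rpoS
knockout) sampled in five growth phases with two biological replicates —
as negative-binomial counts around lognormal gene means, with effects
planted on named gene sets so that every stage of the analysis pipeline
has a known ground truth.

The default template plants:

* ``rpoS_targets`` (300 genes): strongly down (2-8-fold) in the rpoS
  knockout, and subtly down (log2 -0.15, a ~10% decrease) in both the Rsd
  and 6S RNA knockouts in every phase — the regulon-shift signal;
* ``nonadditive`` (100 genes): 4-fold up in the double knockout only;
* ``dose_monotone`` (30 genes): down in the 6S RNA knockout with a
  magnitude that grows each successive phase (log2 -1.0 to -4.8) — these
  play highly expressed polymerase/ribosomal-like genes, so they also get
  the upper range of baseline means by chance of the lognormal draw;
* ``constitutive_sigma70`` (200 genes): no planted effect, a null set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pipeline import PHASES, STRAINS, CountExperiment

__all__ = ["PlantedEffect", "SyntheticSpec", "generate", "default_spec"]


@dataclass(frozen=True)
class PlantedEffect:
    """A log2 effect on one gene set in one strain.

    ``effect`` is either a single log2 fold change applied in every phase,
    a mapping phase -> log2 fold change, or a ``(lo, hi)`` tuple drawing
    one uniform log2 effect per gene (constant across phases).
    """

    gene_set: str
    strain: str
    effect: float | tuple[float, float] | Mapping[str, float]


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 3300
    strains: tuple[str, ...] = STRAINS
    phases: tuple[str, ...] = PHASES
    replicates: int = 2
    baseline_mean_log_mu: float = float(np.log(500.0))
    baseline_mean_log_sigma: float = 0.5
    dispersion: float = 0.05
    library_size_factors: tuple[float, ...] | None = None
    gene_sets: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        for name, genes in self.gene_sets.items():
            if len(genes) >= self.n_genes:
                raise ValueError(f"gene set {name!r} is not smaller than the gene universe")
        known = set(self.gene_sets)
        for eff in self.planted_effects:
            if eff.gene_set not in known:
                raise ValueError(f"planted effect references unknown gene set {eff.gene_set!r}")
            if eff.strain not in self.strains:
                raise ValueError(f"planted effect references unknown strain {eff.strain!r}")

    def n_samples(self) -> int:
        return len(self.strains) * len(self.phases) * self.replicates


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default planted-effect template (see module docstring)."""
    genes = _gene_ids(overrides.get("n_genes", 3300))
    gene_sets = {
        "rpoS_targets": tuple(genes[0:300]),
        "nonadditive": tuple(genes[300:400]),
        "dose_monotone": tuple(genes[400:430]),
        "constitutive_sigma70": tuple(genes[3000:3200]),
    }
    dose_profile = dict(zip(PHASES, (-1.0, -1.8, -2.7, -3.7, -4.8)))
    planted = (
        PlantedEffect("rpoS_targets", "rpoS", (-3.0, -1.0)),
        PlantedEffect("rpoS_targets", "rsd", -0.15),
        PlantedEffect("rpoS_targets", "ssrS", -0.15),
        PlantedEffect("nonadditive", "double", 2.0),
        PlantedEffect("dose_monotone", "ssrS", dose_profile),
    )
    kwargs = dict(gene_sets=gene_sets, planted_effects=planted, seed=seed)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def _effect_matrix(spec: SyntheticSpec, rng: np.random.Generator) -> dict[tuple[str, str], np.ndarray]:
    """Planted log2 effect per (strain, phase), as a vector over genes."""
    genes = _gene_ids(spec.n_genes)
    index = {g: i for i, g in enumerate(genes)}
    effects: dict[tuple[str, str], np.ndarray] = {
        (s, p): np.zeros(spec.n_genes) for s in spec.strains for p in spec.phases
    }
    assigned: dict[tuple[int, str, str], float] = {}
    for eff in spec.planted_effects:
        members = [index[g] for g in spec.gene_sets[eff.gene_set]]
        if isinstance(eff.effect, tuple) and len(eff.effect) == 2 and not isinstance(eff.effect, Mapping):
            lo, hi = eff.effect
            per_gene = rng.uniform(lo, hi, size=len(members))
            per_phase = {p: per_gene for p in spec.phases}
        elif isinstance(eff.effect, Mapping):
            per_phase = {
                p: np.full(len(members), float(v)) for p, v in eff.effect.items()
            }
        else:
            per_phase = {p: np.full(len(members), float(eff.effect)) for p in spec.phases}
        for p, vec in per_phase.items():
            if p not in spec.phases:
                raise ValueError(f"planted effect on unknown phase {p!r}")
            for gi, v in zip(members, vec):
                key = (gi, eff.strain, p)
                if key in assigned and assigned[key] != v:
                    raise ValueError(
                        f"contradictory planted effects on gene {genes[gi]!r}, "
                        f"strain {eff.strain!r}, phase {p!r}: "
                        f"{assigned[key]} vs {v}"
                    )
                assigned[key] = float(v)
                effects[(eff.strain, p)][gi] = v
    return effects


def generate(spec: SyntheticSpec) -> CountExperiment:
    """Draw one count experiment; identical spec (incl. seed) => identical counts."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    base_mu = rng.lognormal(spec.baseline_mean_log_mu, spec.baseline_mean_log_sigma, spec.n_genes)
    effects = _effect_matrix(spec, rng)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for strain in spec.strains:
        for phase in spec.phases:
            for rep in range(1, spec.replicates + 1):
                sample_ids.append(f"{strain}_{phase}_r{rep}")
                meta_rows.append({"strain": strain, "phase": phase, "replicate": rep})
    if spec.library_size_factors is None:
        lib = np.ones(len(sample_ids))
    else:
        lib = np.asarray(spec.library_size_factors, dtype=float)
        if lib.shape != (len(sample_ids),):
            raise ValueError(
                f"library_size_factors must have length {len(sample_ids)}, got {lib.shape}"
            )

    counts = np.empty((spec.n_genes, len(sample_ids)), dtype=np.int64)
    col = 0
    for strain in spec.strains:
        for phase in spec.phases:
            mu_cond = base_mu * np.exp2(effects[(strain, phase)])
            for _ in range(spec.replicates):
                mu = mu_cond * lib[col]
                if spec.dispersion == 0:
                    counts[:, col] = rng.poisson(mu)
                else:
                    # NB with Var = mu + dispersion*mu^2
                    r = 1.0 / spec.dispersion
                    p = r / (r + mu)
                    counts[:, col] = rng.negative_binomial(r, p)
                col += 1

    expt = CountExperiment(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        samples=pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample")),
        gene_sets={k: list(v) for k, v in spec.gene_sets.items()},
        provenance={"generator": "sigmacomp.synthetic.generate", "seed": spec.seed,
                    "spec": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in spec.__dict__.items()
                             if k not in ("gene_sets", "planted_effects")}},
    )
    return expt
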