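import numpy as np
import pytest

from sigmacomp.pipeline import call_de
from sigmacomp.synthetic import (
    PlantedEffect,
    SyntheticSpec,
    _gene_ids,
    default_spec,
    generate,
)


class TestDeterminism:
    def test_same_seed_same_counts(self, tmp_path):
        a = generate(default_spec(seed=3))
        b = generate(default_spec(seed=3))
        assert a.counts.equals(b.counts)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        assert (tmp_path / "a" / "experiment_counts.tsv").read_bytes() == (
            tmp_path / "b" / "experiment_counts.tsv"
        ).read_bytes()

    def test_different_seeds_differ(self):
        assert not generate(default_spec(seed=3)).counts.equals(
            generate(default_spec(seed=4)).counts
        )


class TestSpecValidation:
    def test_contradictory_overlapping_effects_rejected(self):
        genes = _gene_ids(100)
        spec = SyntheticSpec(
            n_genes=100,
            gene_sets={"s1": tuple(genes[:10]), "s2": tuple(genes[5:15])},
            planted_effects=(
                PlantedEffect("s1", "rsd", 1.0),
                PlantedEffect("s2", "rsd", -1.0),
            ),
        )
        with pytest.raises(ValueError, match="contradictory"):
            generate(spec)

    def test_identical_overlapping_effects_allowed(self):
        genes = _gene_ids(100)
        spec = SyntheticSpec(
            n_genes=100,
            gene_sets={"s1": tuple(genes[:10]), "s2": tuple(genes[5:15])},
            planted_effects=(
                PlantedEffect("s1", "rsd", 1.0),
                PlantedEffect("s2", "rsd", 1.0),
            ),
        )
        generate(spec)

    def test_unknown_set_strain_or_size_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(planted_effects=(PlantedEffect("nope", "rsd", 1.0),))
        with pytest.raises(ValueError):
            SyntheticSpec(
                gene_sets={"s": tuple(_gene_ids(3300)[:10])},
                planted_effects=(PlantedEffect("s", "sigmaX", 1.0),),
            )
        with pytest.raises(ValueError):
            SyntheticSpec(n_genes=5, gene_sets={"s": tuple(_gene_ids(5))})


class TestDistribution:
    def test_poisson_limit_replicate_means_match_gene_means(self):
        # dispersion 0, no planted effects: replicate means should sit
        # within 3 standard errors of the gene mean for ~all genes
        spec = SyntheticSpec(n_genes=1000, dispersion=0.0, seed=5)
        expt = generate(spec)
        ids = expt.sample_ids("WT", "EE") + expt.sample_ids("WT", "ME")
        rng = np.random.default_rng(5)
        mu = rng.lognormal(spec.baseline_mean_log_mu, spec.baseline_mean_log_sigma, 1000)
        m = expt.counts[ids].mean(axis=1).to_numpy()
        se = np.sqrt(mu / len(ids))
        frac_in = np.mean(np.abs(m - mu) <= 3 * se)
        assert frac_in >= 0.99

    def test_realized_median_shift_matches_planted_effect(self):
        # high counts, moderate dispersion: the realized median log2fc of
        # a planted set, averaged over 10 seeds, stays within +-0.05 of
        # the planted value
        genes = _gene_ids(800)
        medians = []
        for seed in range(10):
            spec = SyntheticSpec(
                n_genes=800,
                seed=seed,
                baseline_mean_log_mu=float(np.log(1000.0)),
                baseline_mean_log_sigma=0.3,
                dispersion=0.05,
                gene_sets={"set": tuple(genes[:100])},
                planted_effects=(PlantedEffect("set", "rsd", -0.5),),
            )
            de = call_de(generate(spec), "rsd", "S", dispersion=0.05)
            medians.append(float(de.table.loc[genes[:100], "log2fc"].median()))
        assert abs(np.mean(medians) - (-0.5)) <= 0.05

    def test_library_size_factors_scale_counts(self):
        n_samples = len(SyntheticSpec().strains) * 5 * 2
        lib = tuple(2.0 if i == 0 else 1.0 for i in range(n_samples))
        a = generate(SyntheticSpec(n_genes=500, seed=2))
        b = generate(SyntheticSpec(n_genes=500, seed=2, library_size_factors=lib))
        first = b.counts.columns[0]
        ratio = b.counts[first].sum() / a.counts[first].sum()
        assert ratio == pytest.approx(2.0, rel=0.05)
        with pytest.raises(ValueError):
            generate(SyntheticSpec(n_genes=10, library_size_factors=(1.0,)))


class TestDefaultTemplate:
    def test_design_matches_experiment_layout(self, default_expt):
        meta = default_expt.samples
        assert set(meta["strain"]) == {"WT", "rsd", "ssrS", "double", "rpoS"}
        assert set(meta["phase"]) == {"EE", "ME", "TS", "S", "LS"}
        assert meta.groupby(["strain", "phase"]).size().eq(2).all()
        assert default_expt.counts.shape == (3300, 50)

    def test_gene_sets_attached_with_expected_sizes(self, default_expt):
        sizes = {k: len(v) for k, v in default_expt.gene_sets.items()}
        assert sizes == {
            "rpoS_targets": 300,
            "nonadditive": 100,
            "dose_monotone": 30,
            "constitutive_sigma70": 200,
        }

    def test_rpoS_targets_strongly_down_in_rpoS_strain(self, default_expt, default_dispersion):
        de = call_de(default_expt, "rpoS", "S", dispersion=default_dispersion)
        lfc = de.table.loc[default_expt.gene_sets["rpoS_targets"], "log2fc"]
        assert lfc.median() < -1.0  # planted 2-8-fold down

    def test_provenance_embedded(self, default_expt):
        assert default_expt.provenance["seed"] == 1
        assert default_expt.provenance["spec"]["n_genes"] == 3300
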