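import itertools

import numpy as np
import pandas as pd
import pytest

import tmbkit as tk
from tmbkit import association as A


def brute_force_bh(p):
    """Independent step-up oracle: largest k with p_(k) <= k/m * q solves
    q_(i) = min over j >= i of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_single_p(self):
        assert tk.bh_fdr([0.02])[0] == pytest.approx(0.02)

    def test_worked_example_four_values(self):
        q = tk.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(tk.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(A.AssociationError):
            tk.bh_fdr([0.5, 1.5])

    def test_matches_brute_force_on_permutations_of_5(self):
        base = [0.001, 0.011, 0.039, 0.24, 0.9]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(tk.bh_fdr(list(perm)),
                                       brute_force_bh(perm), atol=1e-12)


def build_cohort(n, effect, carrier_frac, diseases=("mel", "lung", "crc"),
                 noise_sd=0.3, seed=0, base=0.8, pc=1.0):
    """Specimen table with one gene whose carriers get +effect log10 TMB.

    The effect is injected on the model's own response scale,
    log10(tmb + pc), so the default-pseudo-count fit is exactly linear and
    parameter recovery is attenuation-free.
    """
    rng = np.random.default_rng(seed)
    disease = rng.choice(diseases, n)
    dis_shift = {d: 0.2 * i for i, d in enumerate(diseases)}
    carrier = rng.random(n) < carrier_frac
    eta = (base + np.array([dis_shift[d] for d in disease])
           + effect * carrier + noise_sd * rng.standard_normal(n))
    spec = pd.DataFrame(
        {"specimen_id": [f"S{i}" for i in range(n)],
         "tmb": np.maximum(10.0 ** eta - pc, 0.0), "disease": disease})
    carriers = {"GENE1": spec.loc[carrier, "specimen_id"].tolist()}
    return spec, carriers, carrier


class TestGeneAssociation:
    def test_exact_constructed_loading(self):
        # carriers sit exactly 10^0.5 above non-carriers within each disease
        # on the pseudo-counted scale
        spec, carriers, _ = build_cohort(200, 0.5, 0.3, noise_sd=0.0, seed=1)
        res = tk.gene_association(spec, carriers)
        assert res.loc[0, "loading"] == pytest.approx(0.5, abs=1e-6)
        assert res.loc[0, "fold_change"] == pytest.approx(10 ** 0.5, rel=1e-6)

    def test_five_carriers_skipped(self):
        spec, _, _ = build_cohort(100, 0.5, 0.0, seed=2)
        carriers = {"RARE": spec["specimen_id"].head(5).tolist()}
        res = tk.gene_association(spec, carriers)
        assert len(res) == 0

    def test_six_carriers_tested(self):
        spec, _, _ = build_cohort(100, 0.5, 0.0, seed=3)
        carriers = {"GENE6": spec["specimen_id"].head(6).tolist()}
        res = tk.gene_association(spec, carriers)
        assert list(res["term"]) == ["GENE6"]

    def test_negative_tmb_rejected(self):
        spec, carriers, _ = build_cohort(50, 0.0, 0.2, seed=4)
        spec.loc[0, "tmb"] = -1.0
        with pytest.raises(A.AssociationError):
            tk.gene_association(spec, carriers)

    def test_recovery_moderate_n(self):
        spec, carriers, _ = build_cohort(1500, 0.5, 0.05, seed=5)
        res = tk.gene_association(spec, carriers)
        assert res.loc[0, "loading"] == pytest.approx(0.5, abs=0.12)
        assert res.loc[0, "q"] < 0.05

    def test_disease_scaling_leaves_loading_unchanged(self):
        # multiplicative invariance holds on the raw log scale, so use a
        # negligible pseudo-count here
        spec, carriers, _ = build_cohort(400, 0.5, 0.2, noise_sd=0.0, seed=6,
                                         pc=0.0)
        ms = A.ModelSpec(pseudo_count=1e-12)
        base = tk.gene_association(spec, carriers, spec=ms)
        scaled = spec.copy()
        factor = scaled["disease"].map({"mel": 3.0, "lung": 0.5, "crc": 10.0})
        scaled["tmb"] = scaled["tmb"] * factor
        res = tk.gene_association(scaled, carriers, spec=ms)
        assert res.loc[0, "loading"] == pytest.approx(
            base.loc[0, "loading"], abs=1e-8)

    def test_fold_change_is_exact_power(self):
        spec, carriers, _ = build_cohort(300, 0.4, 0.2, seed=7)
        res = tk.gene_association(spec, carriers)
        np.testing.assert_allclose(res["fold_change"],
                                   10.0 ** res["loading"], rtol=1e-12)

    def test_singular_design_reported_not_fatal(self):
        # carrier indicator identical to a disease indicator -> collinear
        spec, _, _ = build_cohort(100, 0.0, 0.0, seed=8)
        carriers = {"COLL": spec.loc[spec["disease"] == "mel",
                                     "specimen_id"].tolist()}
        spec_single = spec.copy()
        spec_single["disease"] = np.where(spec["disease"] == "mel",
                                          "mel", "other")
        res = tk.gene_association(spec_single, carriers)
        assert len(res) == 1 and not res.loc[0, "estimable"]


class TestMutationAssociation:
    def annotations(self, **kw):
        rows = {"term": [], "homopolymer_len": [], "dbsnp": []}
        for term, (hp, db) in kw.items():
            rows["term"].append(term)
            rows["homopolymer_len"].append(hp)
            rows["dbsnp"].append(db)
        return pd.DataFrame(rows)

    def test_low_frequency_filtered(self):
        spec, _, _ = build_cohort(3000, 0.0, 0.0, seed=9)
        carriers = {"MUT_RARE": spec["specimen_id"].head(1).tolist()}
        ann = self.annotations(MUT_RARE=(0, False))
        res = tk.mutation_association(spec, carriers, ann)
        assert len(res) == 0  # 1/3000 < 1/2000

    def test_homopolymer_6_filtered(self):
        spec, _, _ = build_cohort(1000, 0.0, 0.0, seed=10)
        carriers = {"MUT_HP": spec["specimen_id"].head(20).tolist()}
        ann = self.annotations(MUT_HP=(6, False))
        res = tk.mutation_association(spec, carriers, ann)
        assert len(res) == 0

    def test_dbsnp_filtered(self):
        spec, _, _ = build_cohort(1000, 0.0, 0.0, seed=11)
        carriers = {"MUT_DB": spec["specimen_id"].head(20).tolist()}
        ann = self.annotations(MUT_DB=(0, True))
        res = tk.mutation_association(spec, carriers, ann)
        assert len(res) == 0

    def test_injected_driver_recovered_and_selected(self):
        spec, carriers, _ = build_cohort(5000, 0.7, 0.01, seed=12)
        carriers = {"DRIVER": carriers["GENE1"]}
        ann = self.annotations(DRIVER=(0, False))
        res = tk.mutation_association(spec, carriers, ann)
        assert res.loc[0, "loading"] == pytest.approx(0.7, abs=0.1)
        assert res.loc[0, "q"] < 0.05
        assert bool(res.loc[0, "selected"])


class TestCooccurrence:
    def build(self, n, seed, dependent=False):
        rng = np.random.default_rng(seed)
        tmb = 10 ** rng.normal(0.6, 0.5, n)
        logit = -3.0 + 0.05 * tmb
        outcome = rng.random(n) < 1 / (1 + np.exp(-logit))
        if dependent:
            gene = outcome & (rng.random(n) < 0.8)
        else:
            gene = rng.random(n) < 0.1
        spec = pd.DataFrame({"specimen_id": [f"S{i}" for i in range(n)],
                             "tmb": tmb})
        carriers = {"G": spec.loc[gene, "specimen_id"].tolist()}
        out = pd.Series(outcome, index=pd.Index(spec["specimen_id"]))
        return out, carriers, spec

    def test_null_gene_rarely_significant(self):
        hits = 0
        for rep in range(100):
            outcome, carriers, spec = self.build(2000, seed=100 + rep)
            res = tk.cooccurrence_test(outcome, carriers, spec)
            if res.loc[0, "estimable"] and res.loc[0, "q"] < 0.05:
                hits += 1
        assert hits <= 10  # q >= 0.05 in >= 90% of null replicates

    def test_perfect_separation_flagged(self):
        outcome, _, spec = self.build(500, seed=200)
        carriers = {"SEP": spec.loc[outcome.to_numpy(),
                                    "specimen_id"].tolist()}
        res = tk.cooccurrence_test(outcome, carriers, spec)
        assert len(res) == 1 and not res.loc[0, "estimable"]

    def test_degenerate_outcome_rejected(self):
        outcome, carriers, spec = self.build(100, seed=201)
        with pytest.raises(A.AssociationError):
            tk.cooccurrence_test(outcome & False, carriers, spec)

    def test_no_cooccurrence_beyond_tmb_at_cohort_scale(self):
        # outcome depends on TMB only; genes independent given TMB
        passed = 0
        for rep in range(5):
            rng = np.random.default_rng(300 + rep)
            n = 1731
            tmb = 10 ** rng.normal(1.0, 0.5, n)
            outcome = rng.random(n) < 1 / (1 + np.exp(-(-2.5 + 0.03 * tmb)))
            if outcome.sum() in (0, n):
                continue
            spec = pd.DataFrame(
                {"specimen_id": [f"S{i}" for i in range(n)], "tmb": tmb})
            carriers = {
                f"G{g}": spec.loc[rng.random(n) < 0.08,
                                  "specimen_id"].tolist()
                for g in range(20)
            }
            res = tk.cooccurrence_test(
                pd.Series(outcome, index=pd.Index(spec["specimen_id"])),
                carriers, spec)
            ok = res[res["estimable"]]
            if (ok["q"] >= 0.05).all():
                passed += 1
        assert passed >= 3  # majority of replicates find nothing


class TestParameterRecovery:
    def test_bias_below_0p02_at_n5000(self):
        loadings = []
        for rep in range(40):
            spec, carriers, _ = build_cohort(5000, 0.5, 0.02,
                                             seed=400 + rep)
            res = tk.gene_association(spec, carriers)
            loadings.append(res.loc[0, "loading"])
        assert abs(np.mean(loadings) - 0.5) < 0.02
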