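import numpy as np
import pandas as pd
import pytest

import encgreg as eg
from encgreg import protocol
from encgreg.io import MISSING, write_dosage_tsv
from encgreg.simulate import ScenarioSpec


def _design_params(sizes, degrees, me, alpha=0.05, beta=0.1):
    return eg.build_design(
        alpha, beta, sizes, list(degrees), empirical_me={r: me for r in degrees}
    )


class TestIntraCohortQC:
    def test_gates_and_reason_codes(self, rng, make_g):
        n = 200
        cols = [
            rng.binomial(2, 0.3, n),            # clean
            rng.binomial(2, 0.005, n),          # fails MAF
            rng.binomial(2, 0.3, n),            # will fail missingness
            np.repeat([0, 2], n // 2),          # fails HWE (no hets)
        ]
        dosages = np.column_stack(cols).astype(np.int8)
        dosages[: n // 10, 2] = MISSING
        g = make_g(dosages)
        qced, excluded = protocol.intra_cohort_qc(g)
        assert qced.snp_ids == ["snp0"]
        reasons = dict(zip(excluded.SNP, excluded.REASON))
        assert reasons["snp1"] == "MAF"
        assert reasons["snp2"] == "MISSINGNESS"
        assert reasons["snp3"] == "HWE"

    def test_hwe_pvalue_equilibrium(self, rng):
        dosages = rng.binomial(2, 0.4, 2000).astype(np.int8)
        assert protocol.hwe_pvalue(dosages) > 1e-4

    def test_all_filtered_raises(self, make_g):
        g = make_g(np.zeros((50, 2), dtype=np.int8), freqs=[0.001, 0.001])
        with pytest.raises(protocol.QCFailure):
            protocol.intra_cohort_qc(g)


class TestCohortEncrypt:
    def _directive(self, g, k=40, seed=77):
        return protocol.Directive(snps=g.snps, k=k, seed=seed)

    def test_missing_directive_snp_fails(self, rng, make_g):
        g = make_g(rng.binomial(2, 0.3, (10, 5)))
        other = make_g(rng.binomial(2, 0.3, (10, 8)))
        with pytest.raises(protocol.QCFailure, match="lacks"):
            protocol.cohort_encrypt(g, self._directive(other), "c1")

    def test_encrypt_dimensions_and_determinism(self, rng, make_g):
        g = make_g(rng.binomial(2, rng.uniform(0.1, 0.5, 30), (12, 30)))
        d = self._directive(g, k=25)
        e1 = protocol.cohort_encrypt(g, d, "c1")
        e2 = protocol.cohort_encrypt(g, d, "c1")
        assert e1.values.shape == (12, 25)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_byte_identical_rerun(self, tmp_path, rng, make_g):
        g = make_g(rng.binomial(2, 0.3, (6, 20)))
        d = self._directive(g, k=10)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        eg.write_encrypted(protocol.cohort_encrypt(g, d, "c1"), pa)
        eg.write_encrypted(protocol.cohort_encrypt(g, d, "c1"), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_allele_orientation_flip(self, rng, make_g):
        """A cohort whose A1/A2 are swapped still encrypts identically."""
        dosages = rng.binomial(2, rng.uniform(0.2, 0.5, 15), (20, 15)).astype(np.int8)
        g = make_g(dosages)
        d = self._directive(g, k=12)
        flipped = eg.GenotypeMatrix(
            g.sample_ids,
            [
                eg.SnpMeta(s.snp_id, s.a2, s.a1, 1 - s.freq_a1, s.callrate)
                for s in g.snps
            ],
            np.where(dosages == MISSING, MISSING, 2 - dosages),
        )
        e_direct = protocol.cohort_encrypt(g, d, "c1")
        e_flipped = protocol.cohort_encrypt(flipped, d, "c1")
        np.testing.assert_allclose(e_direct.values, e_flipped.values, atol=1e-12)

    def test_controls_appended_not_summarized(self, rng, make_g):
        g = make_g(rng.binomial(2, 0.3, (8, 10)))
        ctrl = make_g(rng.binomial(2, 0.3, (2, 10)), prefix="ctrl")
        e = protocol.cohort_encrypt(g, self._directive(g, k=6), "c1", controls=ctrl)
        assert e.n == 10
        assert e.sample_ids[-2:] == ["ctrl0", "ctrl1"]
        # summaries are built before controls are merged
        s, _ = protocol.cohort_summarize(g, "c1")
        assert s.n == 8


class TestEndToEnd:
    def _run_three_cohorts(self, seed, make_genotypes):
        """Three simulated cohorts with planted identical and 1st-degree pairs."""
        rng = np.random.default_rng(seed)
        m, k = 600, 500
        n = {"A": 60, "B": 60, "C": 60}
        p = rng.uniform(0.1, 0.5, m)
        base = {cid: rng.binomial(2, p, (n[cid], m)).astype(np.int8) for cid in n}
        # plant 2 identical pairs A<->B and 3 first-degree pairs A<->C
        base["B"][:2] = base["A"][:2]
        rel, _ = eg.simulate_relative_pair(base["A"][2:5], 1, p, rng)
        base["C"][:3] = rel
        truth = {("A", "B"): [(0, 0, "identical"), (1, 1, "identical")],
                 ("A", "C"): [(2, 0, "1st-degree"), (3, 1, "1st-degree"),
                              (4, 2, "1st-degree")]}
        cohorts = {
            cid: make_genotypes(x, prefix=cid) for cid, x in base.items()
        }
        summaries = [eg.write_summary(g, cid) for cid, g in cohorts.items()]
        panel, fpca_report, _ = protocol.central_intersect(summaries)
        params, directive = protocol.central_design(
            panel, [60, 60, 60], (0, 1), seed=seed, m_budget=len(panel.snps)
        )
        directive = protocol.Directive(snps=directive.snps, k=k, seed=seed)
        encrypted = [
            protocol.cohort_encrypt(g, directive, cid)
            for cid, g in cohorts.items()
        ]
        scores = protocol.central_run(encrypted)
        # thresholds at the panel's m_e (= m, independent SNPs) and the k used
        params = _design_params([60, 60, 60], (0, 1), me=len(directive.snps))
        for d in params.degrees:
            d.threshold = eg.detection_threshold(
                0.05, params.n_comparisons, len(directive.snps), k
            )
        report = protocol.central_report(encrypted, scores, params)
        return report, truth

    def test_planted_relatives_recovered(self, make_g):
        """Planted pairs are reported with the right degrees; miss rate <= beta."""
        found, expected = 0, 0
        spurious = 0
        for seed in range(5):
            report, truth = self._run_three_cohorts(seed + 100, make_g)
            for (ca, cb), pairs in truth.items():
                expected += len(pairs)
                for i, j, label in pairs:
                    hit = report[
                        (report.COHORT1 == ca) & (report.COHORT2 == cb)
                        & (report.ID1 == f"{ca}{i}") & (report.ID2 == f"{cb}{j}")
                    ]
                    if not hit.empty:
                        found += 1
                        assert hit.DEGREE.iloc[0] == label
            spurious += len(report) - sum(len(v) for v in truth.values())
        assert found / expected >= 0.9  # designed beta = 0.1
        assert spurious <= 2

    def test_positive_controls_verified(self, rng, make_g):
        m, k = 400, 400
        p = rng.uniform(0.2, 0.5, m)
        ctrl = make_g(rng.binomial(2, p, (3, m)), prefix="ctrl")
        cohorts = {
            cid: make_g(rng.binomial(2, p, (20, m)), prefix=cid)
            for cid in ("A", "B")
        }
        directive = protocol.Directive(snps=ctrl.snps, k=k, seed=5)
        encrypted = [
            protocol.cohort_encrypt(g, directive, cid, controls=ctrl)
            for cid, g in cohorts.items()
        ]
        scores = protocol.central_run(encrypted)
        params = _design_params([23, 23], (0, 1), me=m)
        report = protocol.central_report(
            encrypted, scores, params, control_ids=["ctrl0", "ctrl1", "ctrl2"]
        )
        ctrl_rows = report[report.ID1.str.startswith("ctrl")]
        assert (ctrl_rows.DEGREE == "identical").all()

    def test_control_failure_raises(self, rng, make_g):
        m = 300
        p = rng.uniform(0.2, 0.5, m)
        cohorts = {
            cid: make_g(rng.binomial(2, p, (15, m)), prefix=cid)
            for cid in ("A", "B")
        }
        directive = protocol.Directive(snps=cohorts["A"].snps, k=200, seed=5)
        encrypted = [
            protocol.cohort_encrypt(g, directive, cid) for cid, g in cohorts.items()
        ]
        # claim a control ID that exists in both cohorts but is unrelated
        for e in encrypted:
            e.sample_ids[0] = "ctrl_shared"
        scores = protocol.central_run(encrypted)
        params = _design_params([15, 15], (0, 1), me=m)
        with pytest.raises(protocol.ControlFailure):
            protocol.central_report(
                encrypted, scores, params, control_ids=["ctrl_shared"]
            )

    def test_no_raw_data_leaves_cohort(self, tmp_path, rng, make_g):
        """The encrypted artifact contains neither dosages nor the raw seed."""
        g = make_g(rng.binomial(2, 0.4, (5, 50)))
        seed = 123456789
        e = protocol.cohort_encrypt(
            g, protocol.Directive(snps=g.snps, k=30, seed=seed), "c1"
        )
        path = tmp_path / "e.tsv"
        eg.write_encrypted(e, path)
        text = path.read_text()
        assert str(seed) not in text
        body = [l for l in text.splitlines() if not l.startswith("#")][1:]
        cells = [c for line in body for c in line.split("\t")[2:]]
        assert not any(c in ("0", "1", "2") for c in cells)

    def test_parsimony_panel_within_exhaustive_panels(self):
        from encgreg.io import SnpMeta

        def s(cid, ids):
            return eg.CohortSummary(
                cid, 10, [SnpMeta(f"rs{j}", "C", "T", 0.3) for j in ids]
            )

        summaries = [s("A", range(12)), s("B", range(4, 16)), s("C", range(8, 20))]
        pars = eg.align_snps(summaries, "parsimony")
        exh = eg.align_snps(summaries, "exhaustive")
        for panel in exh.values():
            assert set(pars.snp_ids) <= set(panel.snp_ids)
            assert len(panel.snps) >= len(pars.snps)


class TestRunConfig:
    def test_flat_key_value_parse(self, tmp_path):
        path = tmp_path / "run.cfg"
        path.write_text(
            "# comment\nrole=central\ndesign=exhaustive\nalpha=0.05\n"
            "beta=0.1\ndegrees=0,1,2\nseed=42\nsummary_dir=/data\n"
        )
        cfg = protocol.RunConfig.from_file(path)
        assert cfg.role == "central"
        assert cfg.design == "exhaustive"
        assert cfg.degrees == (0, 1, 2)
        assert cfg.seed == 42
        assert cfg.paths["summary_dir"] == "/data"

    def test_invalid_role(self):
        with pytest.raises(ValueError):
            protocol.RunConfig(role="observer")


class TestCLI:
    def test_summarize_and_encrypt_round(self, tmp_path, rng, make_g):
        from click.testing import CliRunner
        import json

        from encgreg.cli import main

        g = make_g(rng.binomial(2, rng.uniform(0.2, 0.5, 40), (15, 40)))
        geno = tmp_path / "g.tsv"
        write_dosage_tsv(g, geno)
        runner = CliRunner()
        out_summary = tmp_path / "summary.tsv"
        res = runner.invoke(main, [
            "summarize", "--genotypes", str(geno), "--format", "dosage_tsv",
            "--cohort-id", "A", "--out", str(out_summary),
        ])
        assert res.exit_code == 0, res.output
        assert out_summary.exists()
        directive = tmp_path / "directive.json"
        directive.write_text(json.dumps({
            "snps": [
                {"snp_id": s.snp_id, "a1": s.a1, "a2": s.a2,
                 "freq_a1": s.freq_a1, "callrate": s.callrate}
                for s in g.snps
            ],
            "k": 20,
            "seed": 99,
        }))
        out_enc = tmp_path / "enc.tsv"
        res = runner.invoke(main, [
            "encrypt", "--genotypes", str(geno), "--format", "dosage_tsv",
            "--cohort-id", "A", "--directive", str(directive),
            "--out", str(out_enc),
        ])
        assert res.exit_code == 0, res.output
        e = eg.read_encrypted(out_enc)
        assert e.values.shape == (15, 20)
        header = [l for l in out_enc.read_text().splitlines() if l.startswith("#")]
        assert not any(l.endswith("=99") for l in header)  # raw seed never shipped
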