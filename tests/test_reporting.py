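"""Composition tables, multi-morbidity profiles and the end-to-end run."""

import numpy as np
import pytest
from scipy import stats

import frailnet as fn
from frailnet import vocab
from frailnet.community import Partition

from conftest import make_feature_table


def hand_partition(table, mapping):
    """Partition covering patients (per mapping) plus a dummy modality node."""
    membership = {pid: mapping[pid] for pid in table["patient_id"]}
    return Partition(membership)


class TestCommunityComposition:
    def test_degenerate_partition_all_frail_in_one_community(self):
        table = make_feature_table(
            [{"patient_id": f"F{i}", "frailty_status": "FR"} for i in range(4)]
            + [{"patient_id": f"N{i}"} for i in range(4)]
        )
        part = hand_partition(
            table, {**{f"F{i}": 0 for i in range(4)}, **{f"N{i}": 1 for i in range(4)}}
        )
        by_status, _, _ = fn.community_composition(table, part)
        assert by_status.loc["FR", 0] == pytest.approx(100.0)
        assert by_status.loc["NF", 1] == pytest.approx(100.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(6)
        table = make_feature_table(
            [{"patient_id": f"P{i}",
              "frailty_status": vocab.FRAILTY_STATUSES[i % 4]} for i in range(40)]
        )
        part = hand_partition(
            table, {f"P{i}": int(rng.integers(3)) for i in range(40)}
        )
        by_status, by_comm, _ = fn.community_composition(table, part)
        assert by_status.sum(axis=1).round(6).eq(100.0).all()
        assert by_comm.sum(axis=0).round(6).eq(100.0).all()

    def test_hand_crosstab(self):
        table = make_feature_table(
            [{"patient_id": f"P{i}",
              "frailty_status": "FR" if i < 4 else "NF"} for i in range(10)]
        )
        mapping = {f"P{i}": (0 if i in (0, 1, 4, 5, 6) else 1) for i in range(10)}
        by_status, _, assignment = fn.community_composition(
            table, hand_partition(table, mapping)
        )
        # FR: P0,P1 in c0, P2,P3 in c1 -> 50/50; NF: P4..P6 c0, P7..P9 c1
        assert by_status.loc["FR", 0] == pytest.approx(50.0)
        assert by_status.loc["NF", 0] == pytest.approx(50.0)
        assert assignment == {}  # patients only in this partition

    def test_missing_patient_rejected(self):
        table = make_feature_table([{"patient_id": "A"}, {"patient_id": "B"}])
        with pytest.raises(ValueError):
            fn.community_composition(table, Partition({"A": 0}))


class TestMultimorbidityProfiles:
    def fixture_table(self):
        rows = []
        # 8 FR: 3 with the Circ+EndMet pair, 1 with a novel triple, 4 clean
        for i in range(3):
            rows.append({"patient_id": f"F{i}", "frailty_status": "FR",
                         "categories": ("Circulatory", "EndocrineMetabolic")})
        rows.append({"patient_id": "F3", "frailty_status": "FR",
                     "categories": ("Blood", "Skin", "Infectious")})
        rows += [{"patient_id": f"F{i}", "frailty_status": "FR"} for i in range(4, 8)]
        # 10 NF: 2 with Circ+Resp, 1 single-category (not multi-morbid)
        for i in range(2):
            rows.append({"patient_id": f"N{i}", "frailty_status": "NF",
                         "categories": ("Circulatory", "Respiratory")})
        rows.append({"patient_id": "N2", "frailty_status": "NF",
                     "categories": ("Circulatory",)})
        rows += [{"patient_id": f"N{i}", "frailty_status": "NF"} for i in range(3, 10)]
        return make_feature_table(rows)

    def test_prevalences_match_hand_counts(self):
        profiles, ratio = fn.multimorbidity_profiles(self.fixture_table())
        assert profiles.loc["Circulatory + EndocrineMetabolic", "FR"] == \
            pytest.approx(3 / 8 * 100)
        assert profiles.loc[vocab.OTHER_PROFILE_LABEL, "FR"] == \
            pytest.approx(1 / 8 * 100)
        assert profiles.loc["Circulatory + Respiratory", "NF"] == \
            pytest.approx(2 / 10 * 100)
        # the single-category patient is not a multi-morbid profile
        assert profiles["NF"].sum() == pytest.approx(2 / 10 * 100)
        assert ratio == pytest.approx(100.0)

    def test_subgroup_ratio(self):
        table = self.fixture_table()
        membership = {pid: (0 if pid.startswith("F") else 1)
                      for pid in table["patient_id"]}
        part = Partition(membership)
        _, ratio = fn.multimorbidity_profiles(table, subgroup=0, partition=part)
        overall = 6 / 18  # 6 multi-morbid of 18 patients
        sub = 4 / 8       # 4 multi-morbid of 8 FR patients (community 0)
        assert ratio == pytest.approx(100.0 * sub / overall)

    def test_unknown_subgroup_rejected(self):
        table = self.fixture_table()
        part = Partition({pid: 0 for pid in table["patient_id"]})
        with pytest.raises(ValueError):
            fn.multimorbidity_profiles(table, subgroup=5, partition=part)


class TestRunPipeline:
    def test_deterministic_reports(self, tmp_path):
        config = fn.default_config(200, 9)
        r1 = fn.run_pipeline(config, seed=9, out_dir=tmp_path / "a")
        r2 = fn.run_pipeline(config, seed=9, out_dir=tmp_path / "b")
        assert r1.to_json() == r2.to_json()
        assert (tmp_path / "a" / "report.json").read_text() == \
            (tmp_path / "b" / "report.json").read_text()
        assert (tmp_path / "a" / "network.gexf").exists()

    def test_patient_conservation_and_row_sums(self):
        report = fn.run_pipeline(fn.default_config(1200, 2),
                                 compute_betweenness=False)
        assert int(report.community_sizes.sum()) == 1200
        assert report.composition_by_status.sum(axis=1).round(6).eq(100.0).all()
        assert -1.0 <= report.modularity <= 1.0

    def test_frailty_skewed_modalities_cocluster(self):
        """The frail node should gather its skewed socio-demographic markers.

        The generator channels widowhood and living alone toward FR/PFSN
        patients; the detected community holding the Frail node should
        contain Widowed and LivingAlone in most seeds.
        """
        hits = 0
        for seed in range(1, 6):
            report = fn.run_pipeline(fn.default_config(6000, seed),
                                     compute_betweenness=False)
            assignment = report.modality_assignment
            fr = assignment["Frail"]
            hits += (assignment["Widowed"] == fr
                     and assignment["LivingAlone"] == fr)
        assert hits >= 4

    def test_cocluster_beats_random_assignment(self):
        """Permutation test: co-clustering is not a size artifact (p < 0.01)."""
        rng = np.random.default_rng(0)
        observed, null_ps = 0, []
        n_seeds = 20
        for seed in range(1, n_seeds + 1):
            report = fn.run_pipeline(fn.default_config(2500, seed),
                                     compute_betweenness=False)
            assignment = report.modality_assignment
            fr = assignment["Frail"]
            observed += (assignment["Widowed"] == fr
                         and assignment["LivingAlone"] == fr)
            labels = np.array([c for m, c in assignment.items() if m != "Frail"])
            success = 0
            n_perm = 200
            for _ in range(n_perm):
                pick = rng.choice(len(labels), size=2, replace=False)
                success += (labels[pick[0]] == fr and labels[pick[1]] == fr)
            null_ps.append(success / n_perm)
        p_null = max(max(null_ps), 1e-6)
        pvalue = stats.binom.sf(observed - 1, n_seeds, p_null)
        assert pvalue < 0.01
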