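import dataclasses
import statistics

import numpy as np
import pandas as pd
import pytest

from tipmap.config import SimConfig
from tipmap.simulate import (
    CapacityError,
    GenomeLayout,
    PlantedEffect,
    simulate_all,
    simulate_panel,
    simulate_phenotypes,
    simulate_restriction_map,
    footprint_probe_counts,
)
from tipmap.simulate.signal import compute_footprints, simulate_intensities
from tipmap.assoc import classify_cis_trans
from tipmap.loci import InsertionLocus


def _truth_signature(truth):
    return [
        (i.locus_id, i.chrom, i.position, i.strand, i.family, i.category,
         tuple(bool(v) for v in i.presence))
        for i in truth.insertions
    ]


class TestSimConfig:
    def test_invalid_allele_freq(self):
        with pytest.raises(ValueError):
            SimConfig(allele_freq_range=(0.0, 0.5))

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_reference=-1)

    def test_per_family_counts(self):
        cfg = SimConfig(n_reference={"L1": 5, "AluYa": 2})
        assert cfg.counts_per_family("n_reference") == {
            "L1": 5, "AluYa": 2, "AluYb": 0
        }

    def test_yaml_roundtrip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(str(p))
        loaded = SimConfig.from_yaml(str(p))
        assert loaded == small_config


class TestSimulatePanel:
    def test_determinism(self, small_config):
        _, t1, db1 = simulate_panel(small_config)
        _, t2, db2 = simulate_panel(small_config)
        assert _truth_signature(t1) == _truth_signature(t2)
        pd.testing.assert_frame_equal(db1.records, db2.records)

    def test_conservation_per_family(self, small_config):
        _, truth, _ = simulate_panel(small_config)
        counts = truth.counts_by_category()
        for fam in small_config.families:
            total = sum(
                counts.get((fam, cat), 0)
                for cat in ("reference", "known_polymorphic",
                            "novel_polymorphic", "singleton")
            )
            assert total == 6 + 4 + 4 + 4

    def test_reference_presence_all_ones(self):
        cfg = SimConfig(seed=3, n_cell_lines=20, n_genes=60,
                        n_reference=50, n_known_poly=0, n_novel_poly=0,
                        n_singleton=0, families=("L1",))
        _, truth, _ = simulate_panel(cfg)
        refs = [i for i in truth.insertions if i.category == "reference"]
        assert len(refs) == 50
        assert all(i.presence.all() for i in refs)

    def test_no_singletons_when_count_zero(self, small_config):
        cfg = dataclasses.replace(small_config, n_singleton=0)
        _, truth, db = simulate_panel(cfg)
        db_positions = set(zip(db.records["chrom"], db.records["start"]))
        for ins in truth.insertions:
            if (ins.chrom, ins.position) not in db_positions:
                assert ins.presence.sum() >= 2
        assert not any(i.category == "singleton" for i in truth.insertions)

    def test_category_consistent_with_db_and_presence(self, small_config):
        _, truth, db = simulate_panel(small_config)
        db_pos = set(zip(db.records["chrom"], db.records["start"]))
        for ins in truth.insertions:
            in_db = (ins.chrom, ins.position) in db_pos
            if ins.category in ("reference", "known_polymorphic"):
                assert in_db
            else:
                assert not in_db
            if ins.category == "singleton":
                assert ins.presence.sum() == 1
            if ins.category == "novel_polymorphic":
                assert ins.presence.sum() >= 2

    def test_capacity_error(self):
        cfg = SimConfig(n_genes=2, n_reference=500)
        with pytest.raises(CapacityError):
            simulate_panel(cfg)

    def test_dropped_db_known_poly_relabeled(self):
        cfg = SimConfig(seed=9, n_cell_lines=10, n_genes=80,
                        n_known_poly=30, known_poly_db_fraction=0.5)
        _, truth, db = simulate_panel(cfg)
        db_pos = set(zip(db.records["chrom"], db.records["start"]))
        for ins in truth.insertions:
            if ins.category == "known_polymorphic":
                assert (ins.chrom, ins.position) in db_pos


def _bare_layout(length=1_000_000):
    probes = pd.DataFrame(columns=["chrom", "start", "end", "masked"])
    return GenomeLayout({"chr1": length}, [], [("chr1", 0, length)], probes)


class TestRestrictionMap:
    def test_mean_gap_matches_poisson_process(self):
        # Monte-Carlo vs the exponential-gap oracle over 10 seeds
        gaps = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_enzymes=1)
            rmap = simulate_restriction_map(cfg, _bare_layout())
            sites = rmap.sites["E1"]["chr1"]
            gaps.extend(np.diff(sites).tolist())
        mean = statistics.mean(gaps)
        se = 2500 / np.sqrt(len(gaps))
        assert abs(mean - 2500) < 3 * se

    def test_zero_length_contig(self):
        cfg = SimConfig(seed=0)
        rmap = simulate_restriction_map(cfg, _bare_layout(length=0))
        assert rmap.sites["E1"]["chr1"].size == 0

    def test_same_seed_identical(self):
        cfg = SimConfig(seed=5)
        a = simulate_restriction_map(cfg, _bare_layout())
        b = simulate_restriction_map(cfg, _bare_layout())
        for e in a.sites:
            np.testing.assert_array_equal(a.sites[e]["chr1"], b.sites[e]["chr1"])

    def test_union_is_sorted_superset(self):
        cfg = SimConfig(seed=2)
        rmap = simulate_restriction_map(cfg, _bare_layout())
        union = rmap.union("chr1")
        assert (np.diff(union) > 0).all()
        for e in rmap.sites:
            assert np.isin(rmap.sites[e]["chr1"], union).all()


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(
        seed=13, n_cell_lines=6, n_genes=80,
        n_reference=12, n_known_poly=6, n_novel_poly=6, n_singleton=6,
    )
    return cfg, simulate_all(cfg, with_phenotypes=False)


class TestIntensities:

    def test_signal_separation(self, sim):
        cfg, res = sim
        track = res.tracks[(res.truth.cell_lines[0], "L1")]
        vals = track.probes["intensity"].to_numpy()
        signal_idx = np.zeros(len(vals), dtype=bool)
        starts = track.probes["start"].to_numpy()
        chroms = track.probes["chrom"].to_numpy()
        for ins in res.truth.insertions:
            if ins.family != "L1" or not ins.presence[0]:
                continue
            c, fs, fe = res.truth.footprints[(ins.locus_id, res.truth.cell_lines[0])]
            signal_idx |= (chroms == c) & (starts >= fs - 50) & (starts < fe)
        assert vals[signal_idx].mean() > vals[~signal_idx].mean() + 5

    def test_footprint_median_width_brackets_5kb(self, sim):
        _, res = sim
        widths = {lid: fe - fs for (lid, _), (c, fs, fe) in res.truth.footprints.items()}
        med = statistics.median(widths.values())
        assert 1_000 <= med <= 10_000

    def test_absent_insertion_has_no_footprint(self, sim):
        _, res = sim
        for ins in res.truth.insertions:
            for li, line in enumerate(res.truth.cell_lines):
                key = (ins.locus_id, line)
                assert (key in res.truth.footprints) == bool(ins.presence[li])

    def test_footprint_contains_insertion_position(self, sim):
        _, res = sim
        by_id = res.truth.by_id()
        for (lid, _), (c, fs, fe) in res.truth.footprints.items():
            ins = by_id[lid]
            assert c == ins.chrom
            assert fs <= ins.position <= fe

    def test_footprint_probes_contiguous(self, sim):
        # probes covered by a footprint form one contiguous index run
        _, res = sim
        probes = res.layout.probes
        for lid, (c, fs, fe) in list(
            {k[0]: v for k, v in res.truth.footprints.items()}.items()
        )[:50]:
            sub = probes[(probes["chrom"] == c)]
            covered = sub[(sub["start"] < fe) & (sub["end"] > fs)]
            if len(covered) > 1:
                idx = covered.index.to_numpy()
                assert (np.diff(idx) == 1).all()

    def test_masked_fraction_close_to_config(self, sim):
        cfg, res = sim
        frac = res.layout.probes["masked"].mean()
        n = len(res.layout.probes)
        se = np.sqrt(cfg.masked_probe_fraction * (1 - cfg.masked_probe_fraction) / n)
        assert abs(frac - cfg.masked_probe_fraction) < 4 * se

    def test_track_determinism(self, sim):
        cfg, res = sim
        layout2, truth2, _ = (res.layout, res.truth, None)
        tracks2 = simulate_intensities(cfg, res.truth, res.rmap, res.layout)
        a = res.tracks[(res.truth.cell_lines[1], "AluYa")].probes
        b = tracks2[(res.truth.cell_lines[1], "AluYa")].probes
        pd.testing.assert_frame_equal(a, b)

    def test_footprint_probe_counts(self, sim):
        _, res = sim
        counts = footprint_probe_counts(res.truth, res.layout)
        assert set(counts) == {i.locus_id for i in res.truth.insertions}
        assert all(v >= 0 for v in counts.values())


@pytest.fixture(scope="module")
def panel():
    cfg = SimConfig(
        seed=21, n_cell_lines=20, n_genes=50,
        n_reference=6, n_known_poly=4, n_novel_poly=4, n_singleton=4,
    )
    layout, truth, _ = simulate_panel(cfg)
    return cfg, layout, truth


class TestPhenotypes:

    def test_null_features_independent_of_presence(self, panel):
        # |r| < 0.8 in >= 95% of 100 seeds at n=20 under the null
        cfg, layout, truth = panel
        poly = next(
            i for i in truth.insertions
            if 2 <= i.presence.sum() <= cfg.n_cell_lines - 2
        )
        ok = 0
        for seed in range(100):
            c = dataclasses.replace(cfg, seed=seed, n_null_features=1)
            ph = simulate_phenotypes(c, truth, layout)
            vals = ph.values.iloc[0].to_numpy()
            r = np.corrcoef(poly.presence.astype(float), vals)[0, 1]
            ok += abs(r) < 0.8
        assert ok >= 95

    def test_large_effect_perfect_separation(self, panel):
        cfg, layout, truth = panel
        poly = next(i for i in truth.insertions if 0 < i.presence.sum() < 20)
        eff = PlantedEffect(poly.locus_id, "FX", effect_sd=10.0, cis=False)
        ph = simulate_phenotypes(cfg, truth, layout, effects=[eff])
        vals = ph.values.loc["FX"].to_numpy()
        assert vals[poly.presence].min() > vals[~poly.presence].max()

    def test_cis_anchor_within_window_classified_cis(self, panel):
        cfg, layout, truth = panel
        poly = next(i for i in truth.insertions if i.presence.sum() >= 2)
        eff = PlantedEffect(poly.locus_id, "FC", effect_sd=3.0, cis=True)
        ph = simulate_phenotypes(cfg, truth, layout, effects=[eff])
        anchor = ph.anchor_of("FC")
        locus = InsertionLocus(
            locus_id=poly.locus_id, chrom=poly.chrom,
            start=poly.position, end=poly.position + 1,
            family=poly.family, presence=poly.presence,
        )
        cis, dist = classify_cis_trans(locus, anchor)
        assert cis
        assert dist is not None and dist <= cfg.cis_anchor_window_bp

    def test_unknown_locus_effect_rejected(self, panel):
        cfg, layout, truth = panel
        with pytest.raises(ValueError, match="unknown locus"):
            simulate_phenotypes(
                cfg, truth, layout,
                effects=[PlantedEffect("nope", "F", 1.0)],
            )

    def test_one_value_per_line_per_feature(self, panel):
        cfg, layout, truth = panel
        ph = simulate_phenotypes(cfg, truth, layout)
        assert list(ph.values.columns) == truth.cell_lines
        assert not ph.values.isna().any().any()
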