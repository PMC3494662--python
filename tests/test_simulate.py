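"""Generator audits: determinism, model boundaries, and distributional checks."""

import numpy as np
import pandas as pd
import pytest

from pms_pipeline.datatypes import MISSING, TRANSMISSION_CELLS
from pms_pipeline.mendel import opposite_homozygote_flags
from pms_pipeline.simulate import (
    SIRE_ID,
    SimulationConfig,
    Truth,
    simulate_ai_records,
    simulate_birth_counts,
    simulate_cohort,
    simulate_depth,
    simulate_pairs,
    simulate_sperm_counts,
)
from pms_pipeline.reference import SyntheticReference


def in_deletion_mask(bundle):
    pos = bundle.marker_map.positions
    t = bundle.truth
    return (pos > t.left_flank) & (pos < t.right_flank)


class TestDeterminism:
    def test_same_seed_identical_bundle(self):
        a = simulate_cohort(SimulationConfig(seed=3))
        b = simulate_cohort(SimulationConfig(seed=3))
        assert a.genotypes == b.genotypes
        pd.testing.assert_frame_equal(a.pairs.table, b.pairs.table)
        pd.testing.assert_frame_equal(
            a.depth_carrier.windows, b.depth_carrier.windows
        )
        assert {s: c.counts for s, c in a.counts.items()} == {
            s: c.counts for s, c in b.counts.items()
        }
        assert a.ai_records == b.ai_records
        assert a.sperm_experiments == b.sperm_experiments

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(seed=3))
        b = simulate_cohort(SimulationConfig(seed=4))
        assert a.genotypes != b.genotypes


class TestGenotypeModel:
    def test_affected_have_no_hets_in_deletion_when_clean(self, clean_bundle):
        inside = in_deletion_mask(clean_bundle)
        for aid in clean_bundle.truth.carrier_ids:
            calls = clean_bundle.genotypes.row(aid)[inside]
            assert not (calls == 1).any()
            assert not (calls == MISSING).any()

    def test_affected_hets_in_deletion_rare_at_default(self, bundle7):
        # only genotyping errors may produce in-deletion hets
        inside = in_deletion_mask(bundle7)
        e = bundle7.config.genotyping_error_rate
        n = int(inside.sum()) * len(bundle7.truth.carrier_ids)
        n_het = sum(
            int((bundle7.genotypes.row(a)[inside] == 1).sum())
            for a in bundle7.truth.carrier_ids
        )
        # flips into het happen at rate e/2 per call; allow 3 binomial SDs
        bound = n * e / 2 + 3 * np.sqrt(n * e / 2)
        assert n_het <= bound

    def test_no_mendelian_errors_outside_deletion_when_clean(self, clean_bundle):
        gm = clean_bundle.genotypes
        sire = gm.row(SIRE_ID)
        outside = ~in_deletion_mask(clean_bundle)
        for rec in clean_bundle.pedigree.progeny_of(SIRE_ID):
            flags = opposite_homozygote_flags(sire, gm.row(rec.animal_id))
            assert not flags[outside].any()

    def test_opposite_homozygote_construction(self, clean_bundle):
        # carrier at a marker where sire is hom for one allele and the dam is
        # hom for the other: the call collapses to the maternal homozygote
        gm = clean_bundle.genotypes
        sire = gm.row(SIRE_ID)
        inside = in_deletion_mask(clean_bundle)
        found = 0
        for aid in clean_bundle.truth.carrier_ids:
            dam_id = clean_bundle.pedigree.get(aid).dam_id
            dam, kid = gm.row(dam_id), gm.row(aid)
            sel = inside & (sire == 2) & (dam == 0)
            assert (kid[sel] == 0).all()
            found += int(sel.sum())
        assert found > 0

    def test_zero_mosaicism_has_no_affected(self):
        b = simulate_cohort(SimulationConfig(seed=5, germline_mosaicism=0.0))
        assert b.truth.carrier_ids == []
        assert all(k == 0 for k, _ in b.sperm_experiments)
        assert b.counts["birth"].counts[("F", "del")] == 0
        assert b.counts["birth"].counts[("M", "del")] == 0


class TestTransmissionCounts:
    def test_no_lethality_full_mosaic_carrier_fraction_half(self):
        # m=1, lambda=0: every birth category should hit 1/4
        rng = np.random.default_rng(42)
        totals = np.zeros(4)
        n_rep, n_births = 50, 76
        for _ in range(n_rep):
            totals += simulate_birth_counts(n_births, 1.0, 0.0, rng).as_vector()
        n = n_rep * n_births
        se = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(totals - n * 0.25) <= 3 * se)

    def test_sperm_carrier_fraction_near_half_mosaicism(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(7)
        ks, ns = 0, 0
        for _ in range(200):
            _, exps = simulate_sperm_counts(cfg, rng)
            ks += sum(k for k, _ in exps)
            ns += sum(n for _, n in exps)
        p = cfg.germline_mosaicism / 2
        assert abs(ks / ns - p) <= 3 * np.sqrt(p * (1 - p) / ns)

    def test_male_carrier_birth_fraction(self):
        # mean M-del fraction across seeds ~ (m/2)(1-lambda) of the
        # pre-lethality male expectation, renormalized for survivors
        cfg = SimulationConfig()
        rng = np.random.default_rng(99)
        tot = np.zeros(4)
        for _ in range(200):
            tot += simulate_birth_counts(
                cfg.n_progeny_birth, cfg.germline_mosaicism,
                cfg.male_lethality, rng
            ).as_vector()
        q = cfg.germline_mosaicism / 2
        w = np.array([(1 - q) / 2, q / 2, (1 - q) / 2, q * (1 - cfg.male_lethality) / 2])
        expected = tot.sum() * w / w.sum()
        se = np.sqrt(tot.sum() * (w / w.sum()) * (1 - w / w.sum()))
        assert np.all(np.abs(tot - expected) <= 3 * se)


class TestDepthSimulation:
    def test_carrier_deletion_windows_at_half_depth(self, rng):
        cfg = SimulationConfig()
        truth = Truth("2", cfg.deletion_start_flank, cfg.deletion_end_flank,
                      "ACAT", 0.68, 0.86, 88)
        prof = simulate_depth(truth, cfg, carrier=True, rng=rng)
        w = prof.windows
        inside = (w["start"] > truth.left_flank) & (w["end"] < truth.right_flank)
        depths = w.loc[inside, "depth"]
        se = np.sqrt(cfg.mean_depth / 2 / len(depths))
        assert abs(depths.mean() - cfg.mean_depth / 2) <= 3 * se

    def test_control_flat(self, bundle7):
        w = bundle7.depth_control.windows
        assert abs(w["depth"].mean() - bundle7.config.mean_depth) < 0.2

    def test_zero_depth(self, rng):
        cfg = SimulationConfig(mean_depth=0.0)
        truth = Truth("2", cfg.deletion_start_flank, cfg.deletion_end_flank,
                      "ACAT", 0.68, 0.86, 88)
        prof = simulate_depth(truth, cfg, carrier=False, rng=rng)
        assert (prof.windows["depth"] == 0).all()


class TestPairSimulation:
    def test_spanning_pairs_inflated_by_deleted_length(self, bundle7):
        cfg = bundle7.config
        t = bundle7.truth
        inflation = t.deletion_length - len(t.inserted_seq)
        tab = bundle7.pairs.table
        discordant = tab[
            (tab["clip_side"] == "none")
            & (tab["mate_pos"] > tab["pos"])
            & (tab["insert"] > cfg.insert_mean + 4 * cfg.insert_sd)
        ]
        assert len(discordant) > 0
        implied_frag = discordant["insert"] - inflation
        assert (implied_frag > 2 * cfg.read_len).all()
        assert (implied_frag < cfg.insert_mean + 5 * cfg.insert_sd).all()

    def test_right_clips_carry_insertion_then_right_flank(self, bundle7):
        t = bundle7.truth
        tab = bundle7.pairs.table
        rc = tab[tab["clip_side"] == "right"]
        assert len(rc) > 0
        long_clips = rc[rc["clipped_seq"].str.len() >= 8]
        for seq in long_clips["clipped_seq"]:
            assert seq.startswith(t.inserted_seq)
            rest = seq[len(t.inserted_seq):]
            assert rest == bundle7.reference.fetch(
                t.right_flank, t.right_flank + len(rest) - 1
            )

    def test_no_fragments_gives_empty_evidence(self, rng):
        cfg = SimulationConfig(n_junction_fragments=0, n_background_fragments=0)
        truth = Truth("2", cfg.deletion_start_flank, cfg.deletion_end_flank,
                      "ACAT", 0.68, 0.86, 88)
        ref = SyntheticReference(0)
        ev = simulate_pairs(truth, cfg, rng, ref)
        assert len(ev) == 0


class TestAIRecordGeneration:
    def test_artifact_accounting(self, rng):
        recs = simulate_ai_records(SimulationConfig(), rng)
        failures = [r for r in recs if r.outcome == "failure"]
        assert len(failures) == 35
        assert sum(r.superovulation for r in failures) == 1
        adjacent = [
            r for r in failures
            if not r.superovulation and r.next_event == "ai"
            and r.next_event_day - r.ai_day <= 1
        ]
        assert len(adjacent) == 6
        low_fert = [
            r for r in failures
            if not r.superovulation
            and not (r.next_event == "ai" and r.next_event_day - r.ai_day <= 1)
            and r.consecutive_failures_for_cow >= 3
        ]
        assert len(low_fert) == 8

    def test_clean_failure_bounds_below_truth(self, rng):
        cfg = SimulationConfig()
        recs = simulate_ai_records(cfg, rng)
        clean = [
            r for r in recs
            if r.outcome == "failure" and not r.superovulation
            and r.consecutive_failures_for_cow < 3
            and not (r.next_event == "ai" and r.next_event_day - r.ai_day <= 1)
        ]
        assert len(clean) == 20
        for r in clean:
            gap = r.next_event_day - r.ai_day
            bound = gap - cfg.cycle_days
            if r.next_event == "calving":
                bound -= cfg.gestation_days
            assert 0 < bound <= cfg.max_death_day

    def test_zero_failures(self, rng):
        cfg = SimulationConfig(
            n_ai_failures=0, n_superovulation_artifacts=0,
            n_adjacent_ai_artifacts=0, n_low_fertility_artifact_records=0,
        )
        recs = simulate_ai_records(cfg, rng)
        assert all(r.outcome == "success" for r in recs)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"germline_mosaicism": 1.5},
            {"male_lethality": -0.1},
            {"deletion_end_flank": 49_422_589},
            {"maf_range": (0.3, 0.2)},
            {"n_ai_failures": 5},  # fewer than the 15 artifact records
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()
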