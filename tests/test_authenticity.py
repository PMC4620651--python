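import numpy as np
import pytest

from adnapop import authenticity as au
from adnapop import synthetic_data as sd
from conftest import make_panel, make_reads


def reads_with_counts(panel, n_informative, n_contaminant, tv_reads=0):
    """Read set with given endogenous/contaminant counts spread over a panel.

    ``tv_reads`` of the endogenous reads sit on the transversion locus (if
    any); contaminant reads go to the first transition locus.
    """
    t = panel.table
    tv = t[t["mutation_class"] == "transversion"]
    ti = t[t["mutation_class"] == "transition"]
    rows = []
    k = 0
    for _ in range(n_contaminant):
        row = ti.iloc[0]
        rows.append((f"r{k}", f"{row.chrom}:{row.pos}", row.contaminant_alleles[0]))
        k += 1
    for i in range(tv_reads):
        row = tv.iloc[0]
        rows.append((f"r{k}", f"{row.chrom}:{row.pos}", row.endogenous_allele))
        k += 1
    for i in range(n_informative - n_contaminant - tv_reads):
        row = ti.iloc[i % len(ti)]
        rows.append((f"r{k}", f"{row.chrom}:{row.pos}", row.endogenous_allele))
        k += 1
    return make_reads(rows)


class TestEstimateContamination:
    def test_mtdna_worked_example(self, mito_panel):
        reads = reads_with_counts(mito_panel, 1959, 10, tv_reads=97)
        est = au.estimate_contamination(reads, mito_panel)
        assert est.informative_reads == 1959
        assert est.contaminant_reads == 10
        assert round(est.estimate_pct, 2) == 0.51

    def test_transversion_only_worked_example(self, mito_panel):
        reads = reads_with_counts(mito_panel, 1959, 10, tv_reads=97)
        est = au.estimate_contamination(reads, mito_panel, transversions_only=True)
        assert est.informative_reads == 97
        assert est.estimate_pct == 0.0

    def test_all_contaminant_boundary(self, mito_panel):
        reads = reads_with_counts(mito_panel, 5, 5)
        est = au.estimate_contamination(reads, mito_panel)
        assert est.estimate_pct == 100.0

    def test_third_allele_reads_uninformative(self, mito_panel):
        # endogenous A / contaminant G; a C is neither class
        rows = [("r0", "MT:1000", "C"), ("r1", "MT:1000", "A")]
        est = au.estimate_contamination(make_reads(rows), mito_panel)
        assert est.informative_reads == 1

    def test_multilocus_read_counts_once_and_any_contaminant_wins(self, mito_panel):
        rows = [
            ("r0", "MT:1000", "A"),  # endogenous at one locus ...
            ("r0", "MT:1500", "G"),  # ... contaminant at another: one contam read
            ("r1", "MT:1000", "A"),
        ]
        est = au.estimate_contamination(make_reads(rows), mito_panel)
        assert (est.informative_reads, est.contaminant_reads) == (2, 1)

    def test_no_transversion_loci_is_error(self):
        panel = make_panel([("MT", 1, "A", ["G"], "transition")])
        reads = make_reads([("r0", "MT:1", "A")])
        with pytest.raises(ValueError, match="no informative loci"):
            au.estimate_contamination(reads, panel, transversions_only=True)

    def test_scale_invariance_and_monotonicity(self, mito_panel):
        base = au.estimate_contamination(
            reads_with_counts(mito_panel, 200, 8), mito_panel
        )
        doubled = au.estimate_contamination(
            reads_with_counts(mito_panel, 400, 16), mito_panel
        )
        assert doubled.estimate_pct == pytest.approx(base.estimate_pct)
        more = au.estimate_contamination(
            reads_with_counts(mito_panel, 200, 9), mito_panel
        )
        assert more.estimate_pct >= base.estimate_pct

    def test_jeffreys_interval_brackets_estimate(self, mito_panel):
        est = au.estimate_contamination(
            reads_with_counts(mito_panel, 1000, 10),
            mito_panel,
            interval_method="jeffreys",
        )
        lo, hi = est.interval_pct
        assert 0 <= lo < est.estimate_pct < hi <= 100


class TestXContamination:
    @staticmethod
    def x_panel(n=200):
        return make_panel(
            [("X", 10_000 + 50 * i, "A", ["G"], "transition") for i in range(n)]
        )

    def test_recovers_injected_contamination(self):
        panel = self.x_panel()
        endo = dict(zip(panel.locus_ids, panel.table["endogenous_allele"]))
        cont = {l: a[0] for l, a in zip(panel.locus_ids, panel.table["contaminant_alleles"])}
        c = 0.05
        n = 20_000
        reads, truth = sd.simulate_ancient_reads(
            sd.AncientReadParams(
                n_reads=n, contamination=c, seq_error=0.0,
                emit_lengths=False, emit_damage=False, seed=11,
            ),
            endo,
            cont,
        )
        sex = au.infer_sex({"X": 3.0, "1": 6.0, "2": 6.0}, ["1", "2"], "X")
        ests = au.estimate_x_contamination(reads, {"modern": panel}, sex)
        sd3 = 3 * np.sqrt(c * (1 - c) / n)
        assert abs(ests["modern"].estimate_pct / 100 - c) < sd3

    def test_zero_contamination_null(self):
        panel = self.x_panel(20)
        endo = dict(zip(panel.locus_ids, panel.table["endogenous_allele"]))
        cont = {l: a[0] for l, a in zip(panel.locus_ids, panel.table["contaminant_alleles"])}
        reads, _ = sd.simulate_ancient_reads(
            sd.AncientReadParams(
                n_reads=2000, contamination=0.0, seq_error=0.0,
                emit_lengths=False, emit_damage=False, seed=12,
            ),
            endo,
            cont,
        )
        sex = au.infer_sex({"X": 3.0, "1": 6.0}, ["1"], "X")
        ests = au.estimate_x_contamination(reads, {"modern": panel}, sex)
        assert ests["modern"].estimate_pct == 0.0

    def test_refuses_female_sample(self):
        sex = au.infer_sex({"X": 6.0, "1": 6.0}, ["1"], "X")
        with pytest.raises(ValueError, match="male"):
            au.estimate_x_contamination(
                make_reads([("r0", "X:1", "A")]), {"m": self.x_panel(5)}, sex
            )


class TestInferSex:
    @pytest.mark.parametrize(
        "x,auto,call",
        [(3.1, 6.2, "male"), (6.2, 6.2, "female"), (4.34, 6.2, "ambiguous")],
    )
    def test_threshold_calls(self, x, auto, call):
        sex = au.infer_sex({"X": x, "1": auto}, ["1"], "X")
        assert sex.call == call
        assert sex.ratio == pytest.approx(x / auto)

    def test_zero_autosomal_depth_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            au.infer_sex({"X": 1.0, "1": 0.0}, ["1"], "X")

    def test_recovery_on_simulated_depths(self, rng):
        """Simulated male/female chromosome depths at 6x are recovered >=99%."""
        n_auto, correct = 29, 0
        for i in range(1000):
            male = i % 2 == 0
            # chromosome-level mean depths: ~5 % coefficient of variation
            auto = rng.normal(6.0, 0.3, n_auto).clip(0.1)
            mu_x = 3.0 if male else 6.0
            x = rng.normal(mu_x, 0.05 * mu_x)
            depths = {str(c + 1): auto[c] for c in range(n_auto)}
            depths["X"] = max(x, 0.1)
            call = au.infer_sex(
                depths, [str(c + 1) for c in range(n_auto)], "X"
            ).call
            correct += call == ("male" if male else "female")
        assert correct >= 990


class TestFragmentLengths:
    def test_singleton(self):
        s = au.summarize_fragment_lengths([50], ranges=[(16, 150)])
        assert s.median_bp == 50 and s.fraction_in_range[(16, 150)] == 1.0

    def test_small_arithmetic(self):
        s = au.summarize_fragment_lengths([40, 50, 60], ranges=[(45, 150)])
        assert s.median_bp == 50
        assert s.fraction_in_range[(45, 150)] == pytest.approx(2 / 3)

    def test_lower_median_for_even_counts(self):
        assert au.summarize_fragment_lengths([10, 20]).median_bp == 10

    def test_matches_sort_oracle_on_simulated_lengths(self, rng):
        lengths = rng.integers(16, 151, 10_000)
        ranges = [(16, 150), (20, 150), (30, 60)]
        s = au.summarize_fragment_lengths(lengths, ranges)
        arr = np.sort(lengths)
        assert s.median_bp == arr[(len(arr) - 1) // 2]
        for lo, hi in ranges:
            expect = np.count_nonzero((arr >= lo) & (arr <= hi)) / len(arr)
            assert s.fraction_in_range[(lo, hi)] == pytest.approx(expect)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            au.summarize_fragment_lengths([])


class TestDamageProfile:
    def test_single_observation(self):
        reads = make_reads(
            [("r0", "MT:1", "C")], mismatches=[("r0", "5p", 1, "C", "T")]
        )
        prof = au.damage_profile(reads, 5)
        assert prof.ct_5prime(1) == 1.0

    def test_unobserved_position_is_missing_not_zero(self):
        reads = make_reads(
            [("r0", "MT:1", "C")], mismatches=[("r0", "5p", 1, "A", "A")]
        )
        prof = au.damage_profile(reads, 5)
        assert np.isnan(prof.ct_5prime(1))  # no ref-C observations at pos 1
        assert prof.rate("5p", 1, "A", "G") == 0.0  # ref-A observed, no A->G

    def test_exponential_decay_recovered(self):
        d_max, lam, n = 0.3, 0.5, 20_000
        endo = {"MT:1": "A"}
        reads, _ = sd.simulate_ancient_reads(
            sd.AncientReadParams(
                n_reads=n, damage_max=d_max, damage_lambda=lam,
                seq_error=0.0, emit_lengths=False, damage_k=5, seed=13,
            ),
            endo,
            {"MT:1": "G"},
        )
        prof = au.damage_profile(reads, 5)
        for i in range(1, 6):
            expect = d_max * lam ** (i - 1)
            n_obs = int(
                prof.totals.query(
                    "end == '5p' and position == @i and ref_base == 'C'"
                )["total"].iloc[0]
            )
            sd3 = 3 * np.sqrt(expect * (1 - expect) / n_obs)
            assert abs(prof.ct_5prime(i) - expect) < sd3
            assert abs(prof.ga_3prime(i) - expect) < sd3

    def test_null_damage_shows_only_sequencing_error(self):
        e = 0.001
        reads, _ = sd.simulate_ancient_reads(
            sd.AncientReadParams(
                n_reads=40_000, damage_max=0.0, damage_lambda=0.5,
                seq_error=e, emit_lengths=False, damage_k=3, seed=14,
            ),
            {"MT:1": "A"},
            {"MT:1": "G"},
        )
        # uniform misincorporation: each specific X->Y flip occurs at e/3;
        # pool C->T (5') and G->A (3') over positions for a stable count
        mm = reads.mismatches
        ct = mm[(mm["end"] == "5p") & (mm["ref_base"] == "C")]
        ga = mm[(mm["end"] == "3p") & (mm["ref_base"] == "G")]
        n_obs = len(ct) + len(ga)
        n_hit = int((ct["read_base"] == "T").sum() + (ga["read_base"] == "A").sum())
        expect = e / 3
        sd3 = 3 * np.sqrt(expect * (1 - expect) / n_obs)
        assert abs(n_hit / n_obs - expect) < sd3

    def test_exact_against_brute_force_tally(self, rng):
        bases = np.array(list("ACGT"))
        mm = [
            (f"r{i}", rng.choice(["5p", "3p"]), int(rng.integers(1, 4)),
             str(rng.choice(bases)), str(rng.choice(bases)))
            for i in range(500)
        ]
        reads = make_reads([("r0", "MT:1", "A")], mismatches=mm)
        prof = au.damage_profile(reads, 3)
        for end in ("5p", "3p"):
            for pos in (1, 2, 3):
                for ref in bases:
                    denom = sum(
                        1 for r in mm if r[1] == end and r[2] == pos and r[3] == ref
                    )
                    for read in bases:
                        num = sum(
                            1
                            for r in mm
                            if r[1] == end and r[2] == pos
                            and r[3] == ref and r[4] == read
                        )
                        got = prof.rate(end, pos, ref, read)
                        if denom == 0:
                            assert np.isnan(got)
                        else:
                            assert got == pytest.approx(num / denom)
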