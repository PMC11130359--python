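from collections import Counter

import numpy as np
import pytest

from mitoforge.genome import (
    CircularChromosome,
    CircularInterval,
    GenomeConfiguration,
    canonical_rotation,
    extract_subsequence,
    reverse_complement,
)
from mitoforge.recombination import (
    UnsupportedRecombination,
    build_junctions,
    classify_spanning_reads,
    enumerate_recombinants,
    minor_fraction,
    recombination_screen,
)
from mitoforge.repeats import RepeatPair
from mitoforge.simulate import (
    LongReadSpec,
    MitogenomeSpec,
    PlantedRepeat,
    generate_mitogenome,
    simulate_long_reads,
)

from conftest import random_dna, single_chrom_config


def make_pair(unit1, unit2, orientation, length, mm=0):
    return RepeatPair(
        id="R1", unit1=unit1, unit2=unit2, orientation=orientation,
        alignment_length=length,
        identity_percent=100.0 * (length - mm) / length,
        mismatches=mm, gap_openings=0, score=2 * (length - mm) - 3 * mm,
    )


def base_multiset(config):
    return Counter("".join(c.sequence for c in config.chromosomes))


def basepair_multiset(config):
    """Strand-insensitive counts (A pairs with T, C with G): the quantity an
    inversion conserves on a double-stranded molecule."""
    c = base_multiset(config)
    return {"AT": c["A"] + c["T"], "CG": c["C"] + c["G"], "N": c["N"]}


def direct_repeat_circle(rng, total=10000, rep_len=500, at1=2000, at2=6000):
    bg = random_dna(rng, total)
    rep = random_dna(rng, rep_len)
    seq = bg[:at1] + rep + bg[at1 + rep_len : at2] + rep + bg[at2 + rep_len :]
    cfg = single_chrom_config(seq)
    pair = make_pair(
        CircularInterval("chr1", at1 + 1, at1 + rep_len),
        CircularInterval("chr1", at2 + 1, at2 + rep_len),
        "direct",
        rep_len,
    )
    return cfg, pair, rep


class TestMinorFraction:
    @pytest.mark.parametrize(
        "major,minor,expected",
        [(17, 7, 29.17), (64, 54, 45.76), (61, 41, 40.20), (10, 0, 0.00)],
    )
    def test_values(self, major, minor, expected):
        assert minor_fraction(major, minor) == expected

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            minor_fraction(0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            minor_fraction(-1, 3)


class TestEnumerateRecombinants:
    def test_direct_split_conserves_length(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng)
        ev = enumerate_recombinants(cfg, pair)
        assert ev.event_class == "split"
        product = ev.products[0]
        assert len(product.chromosomes) == 2
        assert sum(len(c) for c in product.chromosomes) == 10000
        assert base_multiset(product) == base_multiset(cfg)

    def test_each_split_product_retains_one_copy(self, rng):
        cfg, pair, rep = direct_repeat_circle(rng)
        product = enumerate_recombinants(cfg, pair).products[0]
        for chrom in product.chromosomes:
            doubled = chrom.sequence * 2
            assert doubled.count(rep) in (1, 2)  # one copy (circularly)

    def test_inversion_involution(self, rng):
        bg = random_dna(rng, 8000)
        rep = random_dna(rng, 400)
        seq = bg[:1500] + rep + bg[1900:4000] + reverse_complement(rep) + bg[4400:]
        cfg = single_chrom_config(seq)
        pair = make_pair(
            CircularInterval("chr1", 1501, 1900),
            CircularInterval("chr1", 4001, 4400, "-"),
            "inverted",
            400,
        )
        ev = enumerate_recombinants(cfg, pair)
        assert ev.event_class == "inversion"
        inv = ev.products[0].chromosomes[0]
        assert len(inv) == len(seq)
        assert basepair_multiset(ev.products[0]) == basepair_multiset(cfg)
        # applying the inversion again restores a rotation of the original;
        # re-locate the (rotated) repeat copies in the product first
        from mitoforge.genome import rotate as rot

        i = (inv.sequence * 2).find(rep)
        assert i >= 0
        aligned = rot(inv, (i - 100) % len(inv))  # unit1 now at 101..500
        j = aligned.sequence.find(reverse_complement(rep))
        assert j > 500
        pair2 = make_pair(
            CircularInterval(aligned.id, 101, 500),
            CircularInterval(aligned.id, j + 1, j + 400, "-"),
            "inverted",
            400,
        )
        cfg2 = GenomeConfiguration("i", (aligned,))
        back = enumerate_recombinants(cfg2, pair2).products[0].chromosomes[0]
        assert canonical_rotation(back).sequence == canonical_rotation(
            cfg.chromosomes[0]
        ).sequence

    def test_fusion_joins_two_circles(self, rng):
        rep = random_dna(rng, 300)
        a = random_dna(rng, 4000)
        b = random_dna(rng, 2500)
        ca = CircularChromosome("cA", a[:1000] + rep + a[1000:])
        cb = CircularChromosome("cB", b[:500] + rep + b[500:])
        cfg = GenomeConfiguration("two", (ca, cb))
        pair = make_pair(
            CircularInterval("cA", 1001, 1300),
            CircularInterval("cB", 501, 800),
            "direct",
            300,
        )
        ev = enumerate_recombinants(cfg, pair)
        assert ev.event_class == "fusion"
        fused = ev.products[0]
        assert len(fused.chromosomes) == 1
        assert len(fused.chromosomes[0]) == len(ca) + len(cb)
        assert base_multiset(fused) == base_multiset(cfg)
        # both repeat copies retained
        doubled = fused.chromosomes[0].sequence * 2
        assert doubled.count(rep) >= 2

    def test_split_then_fusion_returns_rotation(self, rng):
        cfg, pair, rep = direct_repeat_circle(rng)
        split = enumerate_recombinants(cfg, pair).products[0]
        c1, c2 = split.chromosomes
        i1 = c1.sequence.find(rep)
        i2 = c2.sequence.find(rep)
        assert i1 >= 0 and i2 >= 0
        pair2 = make_pair(
            CircularInterval(c1.id, i1 + 1, i1 + len(rep)),
            CircularInterval(c2.id, i2 + 1, i2 + len(rep)),
            "direct",
            len(rep),
        )
        fused = enumerate_recombinants(split, pair2).products[0].chromosomes[0]
        assert (
            canonical_rotation(fused).sequence
            == canonical_rotation(cfg.chromosomes[0]).sequence
        )

    def test_overlapping_units_rejected(self, rng):
        cfg = single_chrom_config(random_dna(rng, 2000))
        pair = make_pair(
            CircularInterval("chr1", 100, 400),
            CircularInterval("chr1", 300, 600),
            "direct",
            301,
        )
        with pytest.raises(ValueError, match="overlap"):
            enumerate_recombinants(cfg, pair)

    def test_cross_circle_inverted_unsupported(self, rng):
        cfg = GenomeConfiguration(
            "two",
            (
                CircularChromosome("cA", random_dna(rng, 2000)),
                CircularChromosome("cB", random_dna(rng, 2000)),
            ),
        )
        pair = make_pair(
            CircularInterval("cA", 100, 400),
            CircularInterval("cB", 300, 600, "-"),
            "inverted",
            301,
        )
        with pytest.raises(UnsupportedRecombination):
            enumerate_recombinants(cfg, pair)


class TestBuildJunctions:
    def test_crossover_construction(self, rng):
        """Circle X-R-Y-R-Z: alt junctions splice tail(X)+R+head(Z) and
        tail(Y)+R+head(Y)."""
        x = random_dna(rng, 1200)
        y = random_dna(rng, 1500)
        z = random_dna(rng, 1100)
        r = random_dna(rng, 400)
        seq = x + r + y + r + z
        cfg = single_chrom_config(seq)
        f = 300
        pair = make_pair(
            CircularInterval("chr1", len(x) + 1, len(x) + 400),
            CircularInterval("chr1", len(x) + 400 + len(y) + 1, len(x) + 400 + len(y) + 400),
            "direct",
            400,
        )
        jm = build_junctions(cfg, pair, flank_length=f)
        assert jm.junctions["ref1"] == x[-f:] + r + y[:f]
        assert jm.junctions["ref2"] == y[-f:] + r + z[:f]
        assert jm.junctions["alt1"] == x[-f:] + r + z[:f]
        assert jm.junctions["alt2"] == y[-f:] + r + y[:f]

    def test_junction_lengths(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng, rep_len=2795, total=20000, at2=9000)
        jm = build_junctions(cfg, pair, flank_length=500)
        for label in ("ref1", "ref2", "alt1", "alt2"):
            assert len(jm.junctions[label]) == 2 * 500 + 2795

    def test_inverted_uses_reverse_complemented_flanks(self, rng):
        bg = random_dna(rng, 6000)
        rep = random_dna(rng, 300)
        seq = bg[:1000] + rep + bg[1300:3000] + reverse_complement(rep) + bg[3300:]
        cfg = single_chrom_config(seq)
        pair = make_pair(
            CircularInterval("chr1", 1001, 1300),
            CircularInterval("chr1", 3001, 3300, "-"),
            "inverted",
            300,
        )
        f = 200
        jm = build_junctions(cfg, pair, flank_length=f)
        chrom = cfg.chromosomes[0]
        # unit2 in its own orientation: upstream = RC of bases after the
        # plus-strand footprint
        up2 = reverse_complement(
            extract_subsequence(chrom, CircularInterval("chr1", 3301, 3300 + f))
        )
        assert jm.junctions["ref2"].startswith(up2)
        assert jm.junctions["alt2"].startswith(up2)

    def test_adjacent_units_warn(self, rng):
        bg = random_dna(rng, 4000)
        rep = random_dna(rng, 200)
        seq = bg[:1000] + rep + rep + bg[1400:]
        cfg = single_chrom_config(seq)
        pair = make_pair(
            CircularInterval("chr1", 1001, 1200),
            CircularInterval("chr1", 1201, 1400),
            "direct",
            200,
        )
        jm = build_junctions(cfg, pair, flank_length=150)
        assert any("degenerate" in w or "coincide" in w for w in jm.warnings)

    def test_flank_too_small_rejected(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng)
        with pytest.raises(ValueError):
            build_junctions(cfg, pair, flank_length=0)


class TestClassifySpanningReads:
    def test_exact_junction_copies_assigned(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng)
        jm = build_junctions(cfg, pair, flank_length=300)
        reads = [
            jm.junctions["alt1"],
            jm.junctions["ref2"],
            reverse_complement(jm.junctions["ref1"]),
        ]
        rs = classify_spanning_reads(reads, jm, min_anchor=100, max_divergence=0.1)
        assert rs.counts == {"ref1": 1, "ref2": 1, "alt1": 1, "alt2": 0}
        assert rs.unassigned == 0

    def test_short_anchor_unassigned(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng)
        jm = build_junctions(cfg, pair, flank_length=300)
        # covers the repeat but ends 50 bp into the downstream flank
        read = jm.junctions["ref1"][: 300 + 500 + 50]
        rs = classify_spanning_reads([read], jm, min_anchor=100, max_divergence=0.1)
        assert rs.unassigned == 1
        assert rs.major_count == rs.minor_count == 0

    def test_single_configuration_has_no_minor(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng, total=12000)
        jm = build_junctions(cfg, pair, flank_length=300)
        pad = (pair.unit1.chrom, pair.unit1.start - 150, pair.unit1.end + 150)
        spec = LongReadSpec(
            mixture={cfg.name: 1.0}, n_reads=150, length_mean=1200, length_sd=100,
            error_rate=0.0, seed=5, span_targets={cfg.name: pad},
        )
        reads, _ = simulate_long_reads([cfg], spec)
        rs = classify_spanning_reads(
            [s for _, s in reads], jm, min_anchor=100, max_divergence=0.1
        )
        assert rs.minor_count == 0
        assert rs.major_count > 0

    def test_mixture_recovery_within_three_se(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng, total=15000, rep_len=300)
        ev = enumerate_recombinants(cfg, pair)
        alt = ev.products[0]
        unit_seq = extract_subsequence(cfg.chromosome("chr1"), pair.unit1)
        tgt = None
        for c in alt.chromosomes:
            i = (c.sequence * 2).find(unit_seq)
            if 0 <= i < len(c):
                tgt = (c.id, i + 1 - 150, i + len(unit_seq) + 150)
                break
        assert tgt is not None
        p_minor = 0.3
        spec = LongReadSpec(
            mixture={cfg.name: 1 - p_minor, alt.name: p_minor},
            n_reads=400, length_mean=800, length_sd=60, error_rate=0.05, seed=17,
            span_targets={
                cfg.name: ("chr1", pair.unit1.start - 150, pair.unit1.end + 150),
                alt.name: tgt,
            },
        )
        reads, _ = simulate_long_reads([cfg, alt], spec)
        jm = build_junctions(cfg, pair, flank_length=300)
        rs = classify_spanning_reads(
            [s for _, s in reads], jm, min_anchor=100, max_divergence=0.15
        )
        n = rs.major_count + rs.minor_count
        se = (p_minor * (1 - p_minor) / n) ** 0.5
        assert abs(rs.minor_count / n - p_minor) <= 3 * se

    def test_empty_junction_model_rejected(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng)
        jm = build_junctions(cfg, pair, flank_length=300)
        with pytest.raises(ValueError):
            classify_spanning_reads([], jm, min_anchor=0)


class TestRecombinationScreen:
    def test_planted_recombining_repeat_flagged(self, rng):
        bg = random_dna(rng, 16000)
        r1 = random_dna(rng, 300)  # recombining
        r2 = random_dna(rng, 300)  # silent
        seq = (
            bg[:2000] + r1 + bg[2300:5000] + r2 + bg[5300:9000] + r1
            + bg[9300:12000] + r2 + bg[12300:]
        )
        cfg = single_chrom_config(seq)
        p1 = make_pair(
            CircularInterval("chr1", 2001, 2300),
            CircularInterval("chr1", 9001, 9300),
            "direct", 300,
        )
        p2 = RepeatPair(
            id="R2",
            unit1=CircularInterval("chr1", 5001, 5300),
            unit2=CircularInterval("chr1", 12001, 12300),
            orientation="direct", alignment_length=300,
            identity_percent=100.0, mismatches=0, gap_openings=0, score=600,
        )
        alt = enumerate_recombinants(cfg, p1).products[0]
        tgt = None
        for c in alt.chromosomes:
            i = (c.sequence * 2).find(r1)
            if 0 <= i < len(c):
                tgt = (c.id, i + 1 - 150, i + 300 + 150)
                break
        spec = LongReadSpec(
            mixture={cfg.name: 0.7, alt.name: 0.3},
            n_reads=120, length_mean=900, length_sd=60, error_rate=0.0, seed=23,
            span_targets={
                cfg.name: ("chr1", 2001 - 150, 2300 + 150),
                alt.name: tgt,
            },
        )
        reads, _ = simulate_long_reads([cfg, alt], spec)
        supports, supported = recombination_screen(
            cfg, [p1, p2], [s for _, s in reads],
            flank_length=300, min_anchor=100, max_divergence=0.1,
        )
        assert supported == ["R1"]
        assert supports["R2"].minor_count < 3

    def test_zero_reads(self, rng):
        cfg, pair, _ = direct_repeat_circle(rng)
        supports, supported = recombination_screen(cfg, [pair], [], flank_length=300)
        assert supported == []
        assert supports["R1"].major_count == 0
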