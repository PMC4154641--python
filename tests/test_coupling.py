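"""Coupled-pair solver: geometry, fixed-point oracle, diagrams."""

import numpy as np
import pytest
from scipy.optimize import brentq

from torsioncouple.coupling import (
    GeneSystem,
    GeometryError,
    SolverOptions,
    build_pair,
    influence_curve,
    phase_diagram,
    solve,
)
from torsioncouple.opening import R_KCAL, SigmoidOpening
from torsioncouple.torsion import TorsionParameters, TranscriptionUnit
from torsioncouple.transcription import PromoterModel


# ---------------------------------------------------------------------------
# independent brute-force oracle for two coupled genes
# ---------------------------------------------------------------------------

def _dg(sigma, op: SigmoidOpening):
    return op.offset + op.slope * sigma + op.amplitude / (1.0 + np.exp(-(sigma - op.sigma_c) / op.width))


def oracle_fixed_points(c12, c21, sigma0, rates, promoters, bounds=(-0.15, 0.05)):
    """All fixed points of the 2-gene system by dense scan + bisection.

    ``c12`` is the sigma increment at promoter 1 per unit rate of gene 2.
    Eliminates k2 = f2(k1) and finds the roots of k1 - f1(f2(k1)).
    """
    lo, hi = bounds

    def rho(sigma, pm):
        beta = 1.0 / (R_KCAL * pm.effective_temperature)
        s = min(max(sigma, lo), hi)
        return np.exp(-beta * (_dg(s, pm.opening) - _dg(sigma0, pm.opening)))

    f1 = lambda k2: rates[0] * rho(sigma0 + c12 * k2, promoters[0])
    f2 = lambda k1: rates[1] * rho(sigma0 + c21 * k1, promoters[1])
    g = lambda k1: f1(f2(k1)) - k1

    beta0 = 1.0 / (R_KCAL * promoters[0].effective_temperature)
    rho_max = np.exp(beta0 * (abs(_dg(sigma0, promoters[0].opening))
                              + max(abs(_dg(lo, promoters[0].opening)),
                                    abs(_dg(hi, promoters[0].opening)))))
    k_hi = rates[0] * rho_max * 1.05
    grid = np.linspace(0.0, k_hi, 4001)
    vals = np.array([g(k) for k in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
    return [(r, f2(r)) for r in roots]


def _coefficients(orientation, d, lengths, torsion):
    """Edge-distance coupling coefficients per unit source rate (re-derived)."""
    la, lb = lengths
    al, b = torsion.alpha, torsion.decay_length
    if orientation == "divergent":
        return (-al * lb * np.exp(-d / b), -al * la * np.exp(-d / b))
    if orientation == "convergent":
        return (al * lb * np.exp(-(d - lb) / b), al * la * np.exp(-(d - la) / b))
    # tandem: promoter 1 (upstream) sees gene 2's trailing lobe at distance d;
    # promoter 2 sees gene 1's leading lobe at distance d - la
    return (-al * lb * np.exp(-d / b), al * la * np.exp(-(d - la) / b))


class TestGeometry:
    def test_divergent_units_transcribe_apart(self):
        sys_ = build_pair("divergent", 500, lengths=(1000, 1000))
        a, b = sys_.units
        assert a.strand == "-" and b.strand == "+"
        assert b.start - a.end == 500  # upstream lobes face each other

    def test_convergent_gap_arithmetic(self):
        sys_ = build_pair("convergent", 2500, lengths=(1000, 1000))
        a, b = sys_.units
        assert a.strand == "+" and b.strand == "-"
        assert b.start - a.end == 500

    def test_tandem_tss_offset(self):
        sys_ = build_pair("tandem", 1500, lengths=(1000, 1000))
        a, b = sys_.units
        assert a.strand == b.strand == "+"
        assert b.start - a.end == 500

    def test_gap_convention_matches_tss(self):
        g = build_pair("convergent", 500, distance_convention="gap")
        t = build_pair("convergent", 2500, distance_convention="tss")
        assert [u.start for u in g.units] == [u.start for u in t.units]

    def test_overlap_rejected(self):
        with pytest.raises(GeometryError):
            build_pair("convergent", 1500, lengths=(1000, 1000))
        with pytest.raises(GeometryError):
            build_pair("tandem", 800, lengths=(1000, 1000))


class TestSolve:
    def test_decoupled_limit_alpha_zero(self, promoter):
        sys_ = build_pair("divergent", 500, promoters=promoter,
                          torsion=TorsionParameters(alpha=0.0))
        res = solve(sys_)
        np.testing.assert_array_equal(res.fold_changes, [1.0, 1.0])
        assert res.converged and res.iterations == 1

    @pytest.mark.parametrize("orientation,d,sigma0",
                             [("divergent", 800, 0.0), ("convergent", 2400, -0.06)])
    def test_symmetric_pair_exactly_symmetric(self, promoter, orientation, d, sigma0):
        sys_ = build_pair(orientation, d, promoters=promoter,
                          torsion=TorsionParameters(sigma0=sigma0))
        res = solve(sys_)
        assert res.converged
        assert res.fold_changes[0] == res.fold_changes[1]
        assert res.promoter_sigma[0] == res.promoter_sigma[1]

    def test_label_swap_permutes_outputs(self, promoter):
        t = TorsionParameters(sigma0=-0.03)
        sys_ = build_pair("tandem", 1600, promoters=promoter, torsion=t,
                          rates=(1.0, 2.0))
        swapped = GeneSystem(units=sys_.units[::-1], promoters=sys_.promoters[::-1],
                             torsion=t)
        r1, r2 = solve(sys_), solve(swapped)
        np.testing.assert_allclose(r1.rates, r2.rates[::-1], rtol=1e-12)

    def test_nonconvergence_flagged(self, promoter):
        sys_ = build_pair("divergent", 400, promoters=promoter)
        res = solve(sys_, SolverOptions(max_iterations=2))
        assert not res.converged

    def test_fixed_point_matches_bruteforce_oracle(self, cmv_like_opening):
        """Randomized pairs: the solver lands on an oracle fixed point."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(24):
            orientation = rng.choice(["divergent", "convergent", "tandem"])
            la, lb = int(rng.integers(600, 1500)), int(rng.integers(600, 1500))
            d_min = {"divergent": 100, "convergent": la + lb + 100, "tandem": la + 100}
            d = int(d_min[orientation] + rng.integers(0, 2500))
            sigma0 = float(rng.uniform(-0.08, 0.0))
            rates = (float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.5, 2.0)))
            t_e = float(rng.uniform(400, 700))
            torsion = TorsionParameters(sigma0=sigma0, alpha=float(rng.uniform(1e-5, 4e-5)))
            pm = PromoterModel(opening=cmv_like_opening, effective_temperature=t_e)
            sys_ = build_pair(orientation, d, lengths=(la, lb), promoters=pm,
                              torsion=torsion, rates=rates)
            res = solve(sys_)
            assert res.converged
            c12, c21 = _coefficients(orientation, d, (la, lb), torsion)
            points = oracle_fixed_points(c12, c21, sigma0, rates, [pm, pm])
            assert points, "oracle found no fixed point"
            dev = min(abs(res.rates[0] - k1) + abs(res.rates[1] - k2)
                      for k1, k2 in points)
            assert dev < 1e-5 * max(1.0, res.rates.max())
            n_checked += 1
        assert n_checked >= 20


class TestInfluenceCurve:
    def test_signs_follow_twin_domain_rule(self, promoter, torsion):
        unit = TranscriptionUnit("g", 0, 1000, "+", 1.0)
        up = influence_curve(unit, promoter, [-500.0, -100.0], 0.0, torsion)
        down = influence_curve(unit, promoter, [1200.0, 2000.0], 0.0, torsion)
        assert (up >= 1.0).all()      # negative lobe helps opening
        assert (down <= 1.0).all()    # positive lobe hinders it

    def test_distance_decay_to_neutrality(self, promoter, torsion):
        unit = TranscriptionUnit("g", 0, 1000, "+", 1.0)
        rho = influence_curve(unit, promoter, [1000 + 20_000.0], 0.0, torsion)
        assert rho[0] == pytest.approx(1.0, abs=1e-8)

    def test_log_fold_change_monotone_in_distance(self, promoter, torsion):
        unit = TranscriptionUnit("g", 0, 1000, "+", 1.0)
        pos = unit.end + np.linspace(0, 5000, 60)
        rho = influence_curve(unit, promoter, pos, -0.04, torsion)
        assert (np.diff(np.abs(np.log(rho))) <= 1e-12).all()

    def test_composition_consistency(self, promoter, torsion):
        from torsioncouple.torsion import field_at
        from torsioncouple.transcription import fold_change

        unit = TranscriptionUnit("g", 0, 1000, "+", 1.0)
        pos = np.array([1500.0, 3000.0])
        rho = influence_curve(unit, promoter, pos, 0.0, torsion)
        direct = fold_change(field_at([unit], pos, torsion), 0.0, promoter)
        np.testing.assert_allclose(rho, direct, rtol=1e-12)

    def test_positions_inside_unit_rejected(self, promoter, torsion):
        unit = TranscriptionUnit("g", 0, 1000, "+", 1.0)
        with pytest.raises(ValueError):
            influence_curve(unit, promoter, [500.0], 0.0, torsion)


class TestRange:
    def test_perturbation_efolds_to_negligible_at_3kb(self, torsion):
        from torsioncouple.torsion import perturbation_at

        unit = TranscriptionUnit("g", 0, 1000, "+", 1.0)
        sigma_a = torsion.alpha * unit.rate * unit.length
        val = perturbation_at(unit, unit.end + 3000, torsion)
        assert val == pytest.approx(sigma_a * np.exp(-3.0), rel=1e-12)

    def test_coupling_negligible_beyond_3kb(self, promoter):
        near = build_pair("divergent", 200, promoters=promoter)
        far = build_pair("divergent", 3000, promoters=promoter)
        log_near = abs(np.log(solve(near).fold_changes[0]))
        log_far = abs(np.log(solve(far).fold_changes[0]))
        assert log_far < 0.05
        assert log_far < log_near


class TestNGene:
    def test_two_gene_chain_reduces_to_pair(self, promoter):
        t = TorsionParameters(sigma0=-0.03)
        pair = build_pair("tandem", 1600, promoters=promoter, torsion=t)
        chain = GeneSystem(units=list(pair.units), promoters=list(pair.promoters),
                           torsion=t)
        np.testing.assert_array_equal(solve(pair).rates, solve(chain).rates)

    def test_remote_third_gene_leaves_pair_unchanged(self, promoter):
        t = TorsionParameters(sigma0=-0.03)
        pair = build_pair("tandem", 1600, promoters=promoter, torsion=t)
        remote = TranscriptionUnit("far", 10_000_000, 10_001_000, "+", 1.0)
        chain = GeneSystem(units=list(pair.units) + [remote],
                           promoters=list(pair.promoters) + [pair.promoters[0]],
                           torsion=t)
        np.testing.assert_allclose(solve(chain).rates[:2], solve(pair).rates, rtol=1e-9)

    def test_three_gene_chain_converges(self, promoter):
        t = TorsionParameters(sigma0=-0.04)
        units = [
            TranscriptionUnit("a", 0, 1000, "+", 1.0),
            TranscriptionUnit("b", 1500, 2500, "+", 1.0),
            TranscriptionUnit("c", 3100, 4100, "-", 1.0),
        ]
        chain = GeneSystem(units=units, promoters=[promoter] * 3, torsion=t)
        res = solve(chain)
        assert res.converged


class TestPhaseDiagram:
    def test_divergent_activation_decays_with_distance(self, promoter):
        diag = phase_diagram("divergent", [300, 1200, 2500], [0.0],
                             promoters=promoter)
        fc = diag.fold_change[0, 0]
        assert (fc > 1.0).all()
        assert (np.diff(fc) < 0).all()

    def test_convergent_repression_strongest_at_prokaryotic_sigma0(self, promoter):
        diag = phase_diagram("convergent", [2300], [-0.06, 0.0], promoters=promoter)
        fc = diag.fold_change[0, :, 0]
        assert fc[0] < 1.0                 # prokaryote-like basal level
        assert fc[0] < fc[1]               # repression deeper than at sigma0=0

    def test_tandem_asymmetry_at_intermediate_sigma0(self, promoter):
        diag = phase_diagram("tandem", [1500], [-0.04], promoters=promoter)
        up, down = diag.fold_change[0, 0, 0], diag.fold_change[1, 0, 0]
        assert up >= 1.0
        assert down <= 1.0

    def test_empty_grid_rejected(self, promoter):
        with pytest.raises(ValueError):
            phase_diagram("divergent", [], [0.0], promoters=promoter)
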