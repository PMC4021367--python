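"""Gene knockout scanning and the three-way essentiality rule."""

import numpy as np
import pandas as pd
import pytest

from thermoflux.core import MetabolicModel, Metabolite, Reaction
from thermoflux.deletions import (COMPLETELY_ESSENTIAL,
                                  CONDITIONALLY_ESSENTIAL, NON_ESSENTIAL,
                                  DeletionReport, classify_essentiality,
                                  delete_gene, disabled_reactions,
                                  scan_single_deletions)
from thermoflux.fba import FbaProblem, apply_medium, solve_fba
from thermoflux.synth import (BCAA_PATHWAY_GENES, CAROTENOID_CHAIN_GENES,
                              FIXTURE_NGAM)


def test_isozyme_pair_survives_single_deletion():
    """A reaction gated by (gene_a or gene_b) stays open minus one."""
    m = MetabolicModel("m")
    m.add_metabolite(Metabolite("A[c]"))
    m.add_reaction(Reaction("R1", {"A[c]": 1.0}, gpr="TTC0049 or TTC0045"))
    knocked = delete_gene(m, "TTC0049")
    assert knocked.reactions["R1"].upper_bound > 0


def test_complex_subunit_deletion_closes_reaction():
    m = MetabolicModel("m")
    m.add_metabolite(Metabolite("A[c]"))
    m.add_reaction(Reaction("R1", {"A[c]": 1.0}, gpr="a and b"))
    knocked = delete_gene(m, "b")
    assert knocked.reactions["R1"].upper_bound == 0
    assert knocked.reactions["R1"].lower_bound == 0


def test_unknown_gene_rejected(fixture):
    with pytest.raises(KeyError):
        delete_gene(fixture.model, "NOT_A_GENE")


def test_chain_cut_kills_growth(chain_model):
    """Sole gene of the only route to biomass: knockout growth 0."""
    knocked = delete_gene(chain_model, "g1")
    sol = solve_fba(knocked)
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


class TestScan:
    def test_report_covers_all_genes_and_media(self, fixture):
        report = scan_single_deletions(fixture.model,
                                       [fixture.dmm, fixture.tm],
                                       ngam=FIXTURE_NGAM)
        assert set(report.genes) == fixture.model.genes
        assert report.media == ["DMM_like", "TM_like"]
        assert ((report.ratios >= -1e-9)
                & (report.ratios <= 1 + 1e-6)).all().all()

    def test_scan_equals_rebuilt_knockouts(self, fixture):
        """Scan results identical to re-building each KO from scratch."""
        report = scan_single_deletions(fixture.model,
                                       [fixture.dmm], ngam=FIXTURE_NGAM)
        wt = report.growth_wt["DMM_like"]
        for gene in sorted(fixture.model.genes)[::5]:  # spot-check subset
            knocked = delete_gene(fixture.model, gene)
            sol = solve_fba(FbaProblem(knocked, fixture.dmm,
                                       ngam=FIXTURE_NGAM))
            mu = sol.objective_value if sol.status == "optimal" else 0.0
            assert report.ratios.loc[gene, "DMM_like"] == pytest.approx(
                mu / wt, abs=1e-7)

    def test_deletion_never_increases_growth(self, fixture):
        report = scan_single_deletions(fixture.model,
                                       [fixture.dmm, fixture.tm],
                                       ngam=FIXTURE_NGAM)
        assert (report.ratios <= 1 + 1e-6).all().all()

    def test_energy_gated_gene_lethal_in_both_media(self, fixture):
        """The NADH-oxidation gene starves ATP: ratio 0 in both media."""
        report = scan_single_deletions(fixture.model,
                                       [fixture.dmm, fixture.tm],
                                       ngam=FIXTURE_NGAM,
                                       genes=["STH0024"])
        assert (report.ratios.loc["STH0024"] <= 1e-6).all()


class TestClassify:
    @staticmethod
    def _report(ratios: dict) -> DeletionReport:
        frame = pd.DataFrame(ratios).T
        frame.columns = ["m1", "m2"]
        return DeletionReport(growth_wt={"m1": 1.0, "m2": 1.0},
                              ratios=frame, disabled={g: [] for g in frame.index})

    def test_threshold_is_less_or_equal(self):
        """Growth at exactly 5% of wild type still counts as essential."""
        report = self._report({"g_at": [0.05, 0.05], "g_above": [0.051, 0.9]})
        cls = classify_essentiality(report)
        assert cls.classes["g_at"] == COMPLETELY_ESSENTIAL
        assert cls.classes["g_above"] == NON_ESSENTIAL

    def test_three_way_split(self):
        report = self._report({"both": [0.0, 0.0], "first_only": [0.0, 1.0],
                               "neither": [1.0, 1.0]})
        cls = classify_essentiality(report)
        assert cls.classes["both"] == COMPLETELY_ESSENTIAL
        assert cls.classes["first_only"] == CONDITIONALLY_ESSENTIAL
        assert cls.classes["neither"] == NON_ESSENTIAL

    def test_gene_outside_all_gprs_non_essential(self, fixture):
        """A gene with no dependent reactions cannot change the optimum."""
        report = scan_single_deletions(fixture.model, [fixture.dmm,
                                                       fixture.tm],
                                       ngam=FIXTURE_NGAM,
                                       genes=["STH0045"])
        # isozyme partner covers it in every medium
        cls = classify_essentiality(report)
        assert cls.classes["STH0045"] == NON_ESSENTIAL


@pytest.fixture(scope="module")
def classification(fixture):
    report = scan_single_deletions(fixture.model,
                                   [fixture.dmm, fixture.tm],
                                   ngam=FIXTURE_NGAM)
    return classify_essentiality(report, fixture.model)


class TestFixtureBiology:
    def test_carotenoid_chain_completely_essential(self, classification):
        """Each single-gene step of the linear carotenoid route is lethal."""
        for gene in CAROTENOID_CHAIN_GENES:
            assert classification.classes[gene] == COMPLETELY_ESSENTIAL

    def test_bcaa_biosynthesis_conditionally_essential(self, classification):
        """Amino-acid supplementation rescues the biosynthetic genes."""
        for gene in BCAA_PATHWAY_GENES:
            assert classification.classes[gene] == CONDITIONALLY_ESSENTIAL

    def test_subsystem_tally_shape(self, classification):
        tally = classification.subsystem_tally
        assert COMPLETELY_ESSENTIAL in tally.columns
        assert tally.loc["carotenoids", COMPLETELY_ESSENTIAL] == 4


def test_essentiality_survives_tightened_uptake(fixture):
    """A gene essential on minimal medium stays essential with less food."""
    lean = fixture.dmm
    leaner_bounds = {rid: (lb / 2, ub) for rid, (lb, ub) in lean.bounds.items()}
    from thermoflux.io import MediumSpec
    leaner = MediumSpec("leaner", bounds=leaner_bounds,
                        unconstrained=list(lean.unconstrained))
    for gene in CAROTENOID_CHAIN_GENES:
        for medium in (lean, leaner):
            knocked = delete_gene(fixture.model, gene)
            sol = solve_fba(FbaProblem(knocked, medium, ngam=FIXTURE_NGAM))
            mu = sol.objective_value if sol.status == "optimal" else 0.0
            assert mu <= 1e-6
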