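"""Built-in example inputs.

Only small, fully itemized configurations live here; survey data for the
worked examples is produced by :mod:`surveyopt.synthetic`.
"""

from __future__ import annotations

from .costs import Combination, CostModel, MethodCost

__all__ = ["amazonian_bat_costs", "amazonian_bat_full_scheme"]


def amazonian_bat_costs() -> CostModel:
    """Cost model of a two-method Amazonian bat survey.

    Mist nets: 18 nets at $20 plus 20 aluminum poles at $8 give a fixed
    cost of $520; each surveyed site takes 2 nights x 4 researchers at
    $48/person-night = $384 variable.  The first mist-net site therefore
    costs $904 and each further site $384.

    Acoustic recorders: six recorders at $60, six 32 GB cards at $67.20
    and one 4 TB disk at $120 give a fixed cost of $883.20; each site
    costs $1062 ($6 plastic bags + $192 installation/retrieval per-diems
    + $864 for 18 expert-days of call identification at $48/day).
    """
    return CostModel(
        {
            "mist_nets": MethodCost(
                fixed=18 * 20 + 20 * 8,
                variable=2 * 4 * 48,
                unit_description="site (2 survey nights, 18 nets, 4 researchers)",
            ),
            "acoustic": MethodCost(
                fixed=6 * 60 + 6 * 67.20 + 120,
                variable=6 + 2 * 2 * 48 + 18 * 48,
                unit_description="site (6 recorders, 2 nights, 18 analysis days)",
            ),
        }
    )


def amazonian_bat_full_scheme(n_sites: int = 12) -> Combination:
    """The full inventorying scheme: every site surveyed with both methods."""
    return Combination({"mist_nets": n_sites, "acoustic": n_sites})
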