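"""Compare idle-enzyme statistics between the activation method and pFBA.

The network offers two routes to biomass: a one-step shortcut catalyzed by
an unmeasured enzyme and a two-step detour through a measured one.  Pure
flux minimization takes the shortcut and leaves the measured enzyme idle;
the activation objective pays a little extra flux to put the expressed
enzyme to work.
"""

from nidleflux.gpr import ConditionProfile
from nidleflux.model_io import MetabolicModel, Metabolite, Reaction
from nidleflux.reports import MethodBundle, compare_report, run_condition

model = MetabolicModel(
    metabolites={
        "A": Metabolite("A", "C6H12O6"),
        "B": Metabolite("B", "C3H4O3"),
        "P": Metabolite("P", "C3H4O3"),
    },
    reactions={
        "EX_A": Reaction("EX_A", {"A": 1.0}, 0.0, 1000.0),
        "SHORT": Reaction("SHORT", {"A": -1.0, "P": 1.0}, 0.0, 1000.0, gpr="g_unmeasured"),
        "LONG1": Reaction("LONG1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, gpr="g_measured"),
        "LONG2": Reaction("LONG2", {"B": -1.0, "P": 1.0}, 0.0, 1000.0),
        "BIOMASS": Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0),
    },
    biomass_reaction_id="BIOMASS",
    id="detour",
)
profile = ConditionProfile(
    condition_id="c1",
    abundances={"g_measured": 1e-3},
    mu=5.0,
    carbon_exchange_id="EX_A",
    uptake_bound=10.0,
)

bundles = []
for method in ("nidle", "pfba"):
    bundle = MethodBundle(method=method)
    bundle.conditions["c1"] = run_condition(model, profile, method)
    bundles.append(bundle)

report = compare_report(bundles)
for method in ("nidle", "pfba"):
    row = report["methods"][method]["per_condition"]["c1"]
    print(
        f"{method:6s} idle = {row['idle_percentage']:5.1f} %   "
        f"active/Ra = {row['active_ra_ratio']:.2f}   "
        f"total flux q = {row['q'] if row['q'] is not None else row['q_prime']:.4f}   "
        f"kapp records = {row['n_kapp']}"
    )
print(
    "\nAn idle enzyme is expressed but none of its expressed-GPR reactions\n"
    "carries flux above 1e-10 mmol/gDW/h.  The activation objective spends\n"
    "2*epsilon extra flux on the detour and thereby recovers a kapp estimate\n"
    "for the measured enzyme that pFBA cannot provide."
)
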