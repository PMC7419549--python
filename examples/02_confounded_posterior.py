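"""Why the posterior is not a diagnosis: confounding.

A shared risk factor R drives both a candidate disease (Dcand) and a
mediating disease (Dmed) that actually causes the symptom S.  Dcand is
strongly correlated with S but has no causal path to it.  The posterior
ranks Dcand above a genuine weak cause (Dweak); both counterfactual
measures score Dcand exactly zero — a disease that cannot have caused any
present symptom cannot constitute a diagnosis.
"""

from twindiag import Evidence, posterior_disease, rank_diseases
from twindiag.fixtures import confounded_network

net = confounded_network("confounded")
ev = Evidence(positive_symptoms={"S"})

print(f"{'disease':8} {'prior':>9} {'posterior':>10} {'sufficiency':>12} {'disablement':>12}")
for d in net.diseases:
    print(
        f"{d:8} {posterior_disease(net, Evidence(), d):9.5f}"
        f" {posterior_disease(net, ev, d):10.5f}"
        f" {dict(rank_diseases(net, ev, 'expected_sufficiency').entries)[d]:12.6f}"
        f" {dict(rank_diseases(net, ev, 'expected_disablement').entries)[d]:12.6f}"
    )

for m in ("posterior", "expected_sufficiency"):
    order = [d for d, _ in rank_diseases(net, ev, m).entries]
    print(f"{m:>21} ranking: {' > '.join(order)}")
print()
print("The posterior promotes Dcand (confounded through R) above Dweak, a")
print("true cause of S; the counterfactual rankings place every disease")
print("with a positive causal score above it.")
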