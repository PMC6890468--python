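# reefbudget

Oxygen budgets for coral reefs shifting from coral to fleshy-algal
dominance. Algae-dominated reefs lose dissolved oxygen through two routes
that bottle incubations can quantify but field oxygen probes miss: the
respiration of the dense heterotrophic microbial community that algal
exudates sustain, and the escape of photosynthetic O₂ as bubbles
(ebullition) nucleating on algal surfaces. `reefbudget` implements the full
chain from incubation endpoints to a predictive budget: cell-specific
metabolic demands, area-normalized O₂ production rates, bubble physics, and
a weighted mixing model of the reef-scale loss fractions — plus a synthetic
data generator that emulates all four experiment designs, so every stage is
testable without external data.

## The model

Each producer class (coral `c`, fleshy algae `a`) carries three rates per
m² of benthos: net dissolved O₂ production ρ^net, gaseous production ρ^gas,
and the microbial respiration it sustains in the 1 m³ boundary-layer water
column, Ω^microb. Gross production is

    O_diss  = ρ^net · 1 m² + Ω^microb · 1 m³
    O_gross = O_diss + ρ^gas · 1 m²

and reef-level quantities mix linearly with cover, C + A = 1:

    O_reef(A) = (1 − A) · O_coral + A · O_algae.

The ebullition loss fraction E(A) = O_reef^gas / O_reef^gross (and the
microbial fraction M(A) analogously) is then a shifted Hill function of
order one in A,

    E(A) = [ (ΔO^gas/ΔO^gross) A + O_coral^gas/ΔO^gross ]
           / [ O_coral^gross/ΔO^gross + A ],     ΔO = O_algae − O_coral,

implemented in both direct and closed form (they are verified identical to
1e−12). The inverse problem is also solved: given loss fractions at covers
0, 0.5 and 1, `solve_gross_ratio` recovers the algae:coral gross-production
ratio r, from which the whole curve can be reconstructed.

Bubble physics: a bubble of radius R_b carries
n_b = (p_e + 2σ_w/R_b)·(4π/3)R_b³/(RT) moles of gas (Laplace pressure +
ideal gas law); dividing a chamber's headspace moles by n_b and the lit
time yields the ebullition rate required to explain the observed gas.

## Worked example

```python
from reefbudget import budget as bd

# loss fractions at 0/0.5/1 algal cover pin down the gross ratio ...
r = bd.solve_gross_ratio(0.104, 0.470, 0.359, algal_cover=0.5)
print(f"algae:coral gross-production ratio r = {r:.3f}")
# ... and with the endpoint ebullition fractions the whole curve follows
model = bd.model_from_fractions(0.104, 0.010, 0.470, 0.197, gross_ratio=r)
for a in (0.0, 0.5, 1.0):
    print(f"A={a:.1f}  M={100*bd.microbial_fraction(model, a):5.1f}%  "
          f"E={100*bd.ebullition_fraction_hill(model, a):5.1f}%")
```

prints

```
algae:coral gross-production ratio r = 2.297
A=0.0  M= 10.4%  E=  1.0%
A=0.5  M= 35.9%  E= 14.0%
A=1.0  M= 47.0%  E= 19.7%
```

i.e. fleshy algae produce ~2.3× more gross O₂ per m² than coral, but at
full algal cover 47.0% of it is respired by microbes and 19.7% leaves as
bubbles — two thirds of gross production never accumulates as dissolved
oxygen.

The full synthetic analysis (simulate → rates → bubbles → budget → stats)
runs as numbered drivers:

```
python analysis/01_simulate.py --seed 42
python analysis/02_incubation_rates.py
python analysis/03_bubble_physics.py
python analysis/04_budget_model.py --seed 42
python analysis/05_statistics.py
```

or in one shot through the CLI: `reefbudget all --out results/run --seed 42`.

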