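# troopmove

Directed movement-influence networks from sparse GPS follows of
group-living animals.

When a primate troop travels, who is actually steering?  `troopmove` takes
the kind of data a single on-foot observer can collect — asynchronous GPS
fixes, one animal at a time, a few minutes apart — and turns it into a
directed, weighted network of movement influence, then asks what
group-level structure that network has: a core of mutually dependent
animals, a single despot, or diffuse influence.  It is written for
behavioural ecologists and movement scientists working with focal-follow
GPS data of stable social groups (the motivating system is a chacma baboon
troop of ~14 adults), and for anyone who wants to stress-test this class
of inference on synthetic groups with known ground truth.

## The model

Each displacement step of a focal animal *i* has an observed unit
direction **v̂**ₜ, modelled without intercept as

    v̂_t = Σ_{j≠i} β_{i,j} v̂_{i,j} + β_cm v̂_cm + β_{t−1} v̂_{t−1}

(directions toward each group member, toward the group centroid, and the
previous heading).  Fits are Bayesian with Normal(0, 0.1) shrinkage priors;
a coefficient whose 99% HPDI excludes zero becomes a directed edge
j → i with weight β_{i,j} (attraction if positive, repulsion if negative).
A group-only model (centroid + persistence) is compared per animal by
WAIC.  Dyadic coefficients are regressed on dominance-rank difference with
varying intercepts (β_{i,j} = β_r Δrank_{i,j} + g_i).  The attraction
network's core/periphery structure is scored by a weighted k-shell
(node score √(degree × strength)) and the statistic
D_core = Σᵢⱼ |xᵢ − xⱼ| over shell values, tested against 10 000 random
reassignments of the observed edge weights.

A built-in agent-based simulator generates troops whose influence matrix
is known, degrades them to the field sampling regime (single observer,
~8–9-minute revisit, GPS noise), and lets every stage be validated by
parameter recovery.  See `docs/methods.md` for the full account.

## Worked example

The numbered scripts under `analysis/` run a complete study on a simulated
12-animal troop with a planted 4-animal core, observed for 100 h at an
8-minute mean revisit:

```sh
python analysis/01_simulate_troop.py
python analysis/02_fit_direction_models.py
python analysis/03_network_structure.py
python analysis/04_rank_effects.py
python analysis/05_recovery_experiments.py
```

Script 01 reports the sampling regime (9 000 fixes, 750 per animal).
Script 02 fits the direction-matching models and prints, per animal, the
usable step count and the WAIC comparison — on this run the full model is
preferred for 12/12 animals (dWAIC 61–107 for the periphery, larger for
the core) and 24 attraction edges survive screening.  Script 03 prints the
core/periphery decomposition:

```
innermost shell (detected core): ['a00', 'a01', 'a02', 'a03']
D_core observed = 80.58; null 95% quantile = 50.41; exceeds: True
```

i.e. the detected core is exactly the planted one and the structure is
stronger than chance weight rearrangements.  Script 04 fits the rank model
on a rank-structured troop and prints

```
rank effect beta_r = 0.0354 (99% HPDI 0.0071 to 0.0670)
variance explained: rank only 20%, rank + individual intercepts 31%
```

— a positive rank effect (lower-ranked animals follow their superiors)
whose interval excludes zero, with individual intercepts adding explained
variance.  Script 05 scores replicate recoveries of all four scenarios and
writes `results/analysis/recovery_summary.csv`; its printed note flags the
correlated-position (downstream) artefact that inflates false-edge rates
in chain-like scenarios — a property of this inference problem that the
package reproduces deliberately.

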