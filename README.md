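# inspectgame

Monte Carlo simulator for **spatial inspection games** — an evolutionary
game-theoretic model of crime, costly punishment and second-order
free-riding on a periodic square lattice.

## The model

Players occupy an L × L lattice with periodic boundaries and play a
pairwise game with their four von Neumann neighbors. Three roles compete
for space:

* **Ordinary people (O)** neither commit nor sanction crime. They lose
  β to a criminal neighbor and otherwise exchange nothing — second-order
  free-riders who benefit from sanctioning without paying for it.
* **Criminals (C)** earn the temptation β from an ordinary victim and
  β − r from a rank-r punisher (the fine is normalized to 1).
* **Punishers** pay an inspection cost r·α in every interaction and
  collect a reward r·(γ − α) from each criminal neighbor. In the
  *uniform* model there is a single full-rank punisher P (r = 1); in the
  *heterogeneous* model punishers come in ranks **L** (r = 1/3),
  **M** (r = 2/3) and **H** (r = 1), carrying proportionally scaled
  cost, reward and fine. A *minimal* variant restricted to {C, L, M} is
  used to study interface motion between competing domains.

Strategies evolve by imitation under the random sequential update
protocol: a random player x collects its payoff Π_x over its four
neighbors, a random neighbor y collects Π_y the same way, and x adopts
s_y with the Fermi probability

    W(s_x ← s_y) = 1 / (1 + exp[(Π_x − Π_y) / K]),   K = 0.5.

One Monte Carlo step (MCS) is L² such elementary updates. The simulator
classifies *phases* (the set of strategies surviving in the stationary
state) across the (β, γ) parameter plane, detects the phase transitions
along a parameter axis, and runs pairwise interface competitions that
expose the cyclic dominance loop O → P → C → O sustaining three-strategy
coexistence.

## Worked example

The minimal C+L+M model at α = 0.5, γ = 1.5 from a prepared
L | M | C stripe state (the `fig5` command also writes PNG snapshots of
the interfaces):

```bash
inspectgame fig5 --beta 0.5 --L 150 --max-mcs 400 --seed 1 --out out/b05
```

```
MCS 20: fractions {'C': 0.2938, 'L': 0.3713, 'M': 0.3348}
MCS 100: fractions {'C': 0.1518, 'L': 0.6008, 'M': 0.2474}
extinction of M at MCS ~210
MCS 400: fractions {'C': 0.4577, 'L': 0.5423, 'M': 0.0}
```

At low temptation (β = 0.5) the mild punisher L outcompetes the more
committed M (lower inspection cost) even though only M can defeat the
criminals — second-order free-riding among punishers. Once M is extinct
the criminals spread against L and settle at a high stationary fraction
f_C ≈ 0.46. At β = 0.9 the C+M alliance instead eliminates C+L
(f_C ≈ 0.39), while the intermediate β = 0.7 keeps all three strategies
alive and yields the most favorable outcome, f_C ≈ 0.27 — punishment
diversity beats any single punisher type.

A phase scan of the full five-strategy model along β at γ = 1.5
(`inspectgame sweep --variant five_strategy --axis beta ...`) passes
through six consecutive transitions,
(O+C+L) → (C+L) → (C+L+M) → (C+M) → (C+M+H) → (C+H) → (C),
with criminals present at every point of the scan.

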