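# Methods

This note records the model, the tunable parameters, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## Model and assumptions

The package treats a protein in solution as a fast-exchange mixture of a
small number of conformational states, each representable by a rigid
ensemble of equally weighted models. Under that assumption, per-residue
Cα fluctuations measured from the pooled coordinates (RMSF_ENS) should
agree with the flexibility the chemical shifts report (RMSF_RCI), and a
NOESY peak is compatible with the mixture if *any* state brings the
corresponding proton pair close — hence the minimum rule when merging
per-state distance summaries. No state populations are estimated: mixing
is 1:1 per model (the combination step pools models with equal weight),
and slow-exchange phenomena (peak doubling) are outside the model.

The Bayesian score is deliberately coarse: recall rescaled over the
scored pool is the NOE likelihood, pTM the prior for global terms, and
|SCC(pLDDT, RCI)| with ⟨pLDDT⟩ the residue-level analogue. Geometric
means keep each factor's influence symmetric; the two data channels are
then averaged. Scores are comparative, not calibrated probabilities —
they rank models within one run (recall_min/recall_max are taken over the
sanity-filtered pool being scored) and are not transferable across runs.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| proton match tolerance | 0.05 | ppm | typical 3D NOESY digital resolution |
| 13C / 15N tolerance | 0.4 / 0.5 | ppm | heteronuclear linewidths |
| distance cutoff | 5.0 | Å | conventional NOE observability limit (hard ceiling 6.5) |
| ensemble summarizer | midrange | — | (min+max)/2 across models; per-model recall used for scoring |
| equivalent protons | min | — | pseudo-atom-style minimum; r⁻⁶ sum selectable |
| RCI cap / smoothing | 0.6 / 3-point | — | reciprocal diverges at vanishing secondary shifts; cap then smooth, in that order |
| RCI → RMSF | 12.7 | Å | linear conversion of the capped, smoothed index |
| RCI weights A–F | 0.74/0.72/0.13/0.38/0.15/0.91 | — | literature-style relative sensitivities (Cα, CO, Cβ, N, NH, Hα); packaged, user-replaceable |
| low-pLDDT exclusion | ≤ 50 | — | comparison-interval statistics only |
| clustering | Ward, k=4 | — | k is data-set specific; the synthetic runs use k=2 |
| models per candidate state | 5 | — | top-k by P(model\|NMR), ties by pTM then model id |
| well-defined RMSF cutoff | 2.0 | Å | ranges: gaps ≤ 2 bridged, runs < 4 dropped |
| CCC adequacy threshold | 0.4 | — | below it the representation is flagged inadequate |

The RCI weighting coefficients and random-coil reference shifts are not
uniquely standardized across implementations; the packaged values are
documented literature-style defaults and both are fully configurable.
Exact numerical parity with any particular RCI server is therefore not a
goal, and published recall values from external matching engines are only
reproducible when their (unpublished) tolerances are supplied.

## Numerical choices

* **Superposition** is closed-form Kabsch (SVD with determinant
  correction); degenerate/collinear inputs are rejected. Ensemble RMSF
  first aligns every model to the first model, then re-aligns twice onto
  the running mean — the result is exactly invariant under rigid motion
  of any input and effectively independent of model order.
* **Alignment ranges for state combination** default to the residues the
  *shift data* call rigid (RMSF_RCI ≤ 2 Å). A model-derived core fails
  precisely when multiple states exist: a hinge between two similar-size
  domains is largely absorbed by a global fit (on the synthetic hairpin
  the pooled tail RMSF drops from ~4.8 Å head-aligned to ~1 Å global), so
  anchoring on the experiment avoids the circularity. The geometric
  heuristic and a user override remain available.
* **Eq.-style score algebra**: the RCI term defaults to
  sqrt(|SCC|·⟨pLDDT⟩), symmetric with the NOE term; the alternative
  |SCC|·⟨pLDDT⟩^½ reading is a config switch (`eq9_variant`). Degenerate
  cases are defined, not fatal: constant pLDDT → SCC undefined → score 0
  with warning; recall_max = recall_min → likelihood 0.5 for all models.
* **Lin's CCC** uses population (1/N) moments; the sample-moment variant
  differs by O(1/N) and would shift the bound CCC ≤ |PCC| checks.
* **Greedy combination**: acceptance requires a *strict* CCC increase;
  all candidates failing to improve in a round are permanently
  eliminated; ties resolve by candidate rank. A non-positive state-1 CCC
  exits immediately with a failure flag.
* **Ambiguous peaks** count once: a peak is explained if any candidate
  pair is short. Diagonal (same-group) pairs are excluded. Protons
  missing from a model fall back to the bonded heavy atom with a 1 Å
  pseudo-atom correction, with a warning.
* **TM-score** uses d0(L) = 1.24(L−15)^⅓ − 1.8 floored at 0.5 Å, seeds of
  several fragment lengths with iterative extension, normalized by the
  reference length.

## The synthetic test bed

`synthdata` builds a packed helix-hairpin peptide (ideal internal
coordinates, NeRF chain construction; backbone + Cβ + amide H + Hα +
alanine methyls) whose turn torsions were chosen, by a clash-checked
search, to pack the two helices (~17 long-range Cα contacts). State 2
rotates the hinge ψ by +25°, opening the hairpin (~10 contacts). Each
model draws a per-model hinge jitter (σ = 3°) — the continuous spread
real enhanced-sampling pools show, and the reason a *single* state's RMSF
correlates positively with true flexibility, which the combination step's
CCC > 0 gate requires — plus per-residue rigid coordinate noise
(σ = 0.3 Å). Noise is per residue, not per atom: atomically independent
noise at this amplitude destroys local stereochemistry and would trip the
D-chirality filter on every model, while the Cα closed form
RMSF = √(d²/4 + 3σ²) is unchanged.

Ground truth is exact: the pooled RMSF is computed from the noiseless
per-model coordinates plus the analytic noise term. Synthetic shifts
invert the RCI formula (secondary-shift magnitudes scaled so protons stay
within ~1.5 ppm of random coil while heavy atoms absorb the remainder),
so the RCI pipeline recovers the planted RMSF with CCC > 0.99; NOESY
peaks are back-calculated from the merged true states. pLDDT is assigned
anti-monotone to true RMSF (range 55–95) and pTM per state (0.90/0.85),
exercising every term of the selection score. A decoy generator hinges
the hairpin 3× past both states, losing the packing contacts that
generated the data — its recall falls strictly below either true state.
(A decoy hinged in the *closing* direction only gains contacts; recall
cannot punish spurious compactness — that is precision's job.)

What passing these tests shows: the machinery is internally consistent,
the planted two-state signal is recovered end-to-end in ≥ 9/10 seeds, and
every closed form holds. What it does not show: performance on real
data — the toy has no sidechain rotamers beyond Ala methyls, no shift
degeneracy from chemical similarity, no spectral artifacts or missing
assignments, and its shifts are internally consistent by construction
rather than physically predicted (no ring currents or sequence-dependent
corrections).

## Known limitations

* The matching engine reconstructs standard recall/precision semantics
  but does not implement completeness-normalized scores (no random-coil
  baseline), so F is reported un-normalized.
* Well-defined-range detection is a threshold heuristic with override,
  not a full cyclic-coordinate analysis.
* Equivalent-proton groups are derived from atom names (methyls,
  degenerate Phe/Tyr ring pairs, geminal pairs sharing one assignment);
  stereospecific assignments are not distinguished.
* Insertion codes, altloc ensembles (first altloc wins), and mmCIF
  writing are unsupported.
* Sequence harmonization requires identical numbering; there is no
  alignment.
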