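# Methods

## The modeling procedure

`cwqsar` fits a one-descriptor regression

    endpoint = C0 + C1 · DCW(T, N)

where the optimal descriptor DCW is the sum of correlation weights of the
SMILES attributes present in a molecule.  Attributes are of two kinds:
single SMILES atoms (tokens) and ordered pairs of tokens adjacent in the
SMILES line.  A molecule with n tokens therefore contributes n single-atom
occurrences and n−1 pair occurrences, each adding its weight to DCW with
multiplicity.  The method makes no use of molecular graphs, 3D structure or
computed descriptors: the SMILES line itself is the feature source, which
keeps every feature human-readable and the whole model auditable.

Model building uses four disjoint random subsets of roughly a quarter each:

* **active training** — the weights are optimized against it and the final
  regression is fitted on it;
* **passive training** — a second training set acting as an inspector: the
  target function rewards agreement between the two, penalizing weights that
  fit the active set only;
* **calibration** — steers the predictive-potential criteria (IIC/CII/CCCP)
  during optimization;
* **validation** — never visible to the optimizer; used once, at the end,
  to measure predictivity.  Isolation is structural: `optimize()` accepts
  only the three building subsets, so validation leakage is impossible by
  construction, not by discipline.

### Tokenization

A token is one character unless it belongs to the multi-character table:
two-letter element symbols (Cl, Br, Si, Se), the `@@` chirality mark, `%`
followed by two ring-closure digits, or an entire bracket atom `[...]`.
This is the minimal chemically coherent reading of "a group of symbols that
cannot be considered separately"; the table is a module-level constant and
easy to extend.  The `.` character is reserved as key padding, so
multi-component SMILES are rejected rather than silently mis-featurized.

Attribute keys use a fixed 12-character dialect built from 4-character
`.`-padded fields (`Cl..........`, `c...1.......`).  Pair keys are
canonical: the two fields are ordered by descending byte value, making the
key independent of reading direction.  Tokens longer than four characters
(e.g. `[NH3+]`) are folded to a stable 4-character code (first three
characters + `#`); collisions are possible in principle and logged at debug
level, but do not occur with ordinary organic SMILES.

### Rare-attribute blocking

An attribute is rare if its frequency in the active training set is below
the threshold T (default 5, strict inequality: a count of exactly T stays
active).  Rare attributes are blocked — their weights are pinned to zero —
as are attributes never seen in the active set.  "Frequency" here means the
number of molecules containing the attribute (presence counting), the same
notion the applicability-domain probabilities use; occurrence counting is
available via `count_mode="occurrence"`.

### Target functions and optimization

    TF0 = R_AT + R_PT − |R_AT − R_PT| · 0.1
    TF1 = TF0 + IIC · 0.3      TF2 = TF0 + CII · 0.3      TF3 = TF0 + CCCP · 0.3

R_AT and R_PT are Pearson correlations between the observed endpoint and the
raw descriptor on the two training sets (the regression is monotone in the
descriptor, so correlation needs no intermediate fit).  The criterion term
is computed on the calibration set, using calibration predictions from the
active-set regression, refreshed at every proposal by default
(`refresh="epoch"` trades exactness of the criterion term for speed by
holding it fixed within an epoch).

The optimizer is a plain accept-if-not-worse Monte Carlo hill climb.  One
epoch visits every non-blocked attribute once in seeded-random order and
proposes `CW' = CW + step_size · u`, `u ~ U(−1, 1)`; the move is kept iff
the target function does not decrease.  Defaults: N = 15 epochs, weights
initialized to 1.0 (making the initial descriptor a token count — a sane
baseline; `init="uniform"` draws from U(−1, 1) instead), `step_size = 1.0`.
The step size deserves a note: with one proposal per attribute per epoch,
a 15-epoch budget gives each weight only 15 chances to move.  A step of 0.1
caps total displacement near 1.5 and in practice stalls far short of useful
weights (validation R² ≈ 0.13 on the standard recovery fixture); a step of
1.0 lets weights traverse the few units they need and reaches validation
R² ≈ 0.87–0.95.  Acceptance of exact ties is deliberate: it lets the search
drift across plateaus.  The accepted-move TF sequence is recorded and is
non-decreasing by construction (asserted in tests); with `refresh="epoch"`
the sequence may step down at epoch boundaries when the cached criterion is
refreshed.

### Statistics

For each subset the package reports n, R², CCC, IIC, CII, Q², CCCP, RMSE,
MAE, F and the number of active attributes.  Residuals are
`observed − calculated` everywhere.

* **R²** — squared Pearson correlation of observed vs calculated.
* **CCC** — Lin's concordance, `2·cov / (var_o + var_c + (mean_o − mean_c)²)`,
  with population (1/n) moments.
* **Q²** — leave-one-out cross-validated R² of the one-variable regression
  of observed on calculated, `1 − PRESS/SS_tot` with SS_tot about the full
  mean.
* **F** — Fisher ratio `r²(n−2)/(1−r²)`; a perfect fit reports infinity.
* **IIC** — `r · min(MAE⁻, MAE⁺) / max(MAE⁻, MAE⁺)`, where MAE⁻/MAE⁺ are
  the mean absolute residuals of the negative and non-negative residual
  classes.  If either class is empty (uniformly biased or perfect fits) the
  index is 0 by convention.
* **CII** — `1 − Σ_k max(0, R²₋ₖ − R²)`: each point whose removal *raises*
  R² is an opponent of the correlation and its protest lowers the index.
* **CCCP** — `(supporters − opponents)/n`, a point being a supporter when
  its removal lowers R² and an opponent when it raises it; exact ties and
  degenerate removals count to neither side.

IIC, CII and CCCP are reconstructions: their defining papers are separate
from the protocol this package implements, which names but does not print
them.  The forms above satisfy the documented ranges and the published
narrative (CII built from supporters only, CCCP from supporters and
opponents), and they are validated against independent brute-force
leave-one-out oracles, not against published numbers.  The CCCP form is the
least certain of the three.  A practical consequence, measured on synthetic
data: CCCP rewards the supporter/opponent *balance* rather than correlation
magnitude, so under a well-specified linear ground truth TF3 tends to trade
calibration R² away (TF3 ≥ TF0 in 0/3 seeds of the adversarial-calibration
experiment) while TF2 (CII) showed the augmentation effect in 3/3 seeds.
Any claim of equivalence with the original CCCP-guided software would
require checking against its reference implementation.

The leave-one-out R² values inside CII and CCCP are computed by downdating
the five running sums (O(n) per series rather than O(n²)); the brute-force
recomputation kept in the test suite is the correctness oracle for this
fast path.

### Applicability domain

Each attribute's statistical defect is

    d_k = |P − P′|/(N + N′) + |P − P″|/(N + N″) + |P′ − P″|/(N′ + N″)

with P, P′, P″ the presence probabilities and N, N′, N″ the presence counts
in the active, passive and calibration sets; a term with zero frequency sum
contributes zero.  The absolute values make d_k a genuine defect (non-
negative, zero iff the prevalences agree); d_k is symmetric under subset
permutation.  A molecule's defect D_j sums d_k over its *distinct*
non-blocked attributes, and the molecule is inside the domain iff
D_j < 2·D̄, strictly, where D̄ is the mean D_j over the active training set
(the only subset guaranteed present at deployment).

One structural observation, measured on fixtures: a single attribute's
defect is bounded by 2/n_subset, so one discordant attribute can flag a
molecule only when molecules carry few attributes (short SMILES).  For
long molecules the domain responds to accumulated disagreement across many
attributes rather than to any single rare fragment.

### Mechanistic interpretation

Running the optimization several times with derived seeds ("probes") gives
independent weight vectors.  An attribute whose weight is strictly positive
in every probe is a promoter of endpoint increase; strictly negative in
every probe, a promoter of decrease; anything else — mixed signs or an
exact zero in any probe — is unclear.  Reports order attributes as
increase block, decrease block, then unclear, each by descending
active-set frequency.

## The synthetic data generator

There is no bundled experimental dataset; fixtures are generated.  Each
molecule is a seeded-random token string over a 10-token vocabulary
(C, c, N, O, Cl, S, =, 1, parentheses), 8–20 tokens long, with parentheses
and ring digits emitted in matched pairs so every string tokenizes and
round-trips.  Endpoints are

    endpoint = c0 + c1 · Σ_k n_k · w_true(k) + ε,   ε ~ N(0, sd)

with ground-truth weights drawn from U(−1, 1) on the single-atom attributes
plus eight random pairs, noise sd 0.2 by default, and c0 = 0, c1 = 1.  This
scale yields endpoint spreads of a few log units, matching a realistic
pLC50 table.  Because `(` and `)` appear equally often in every molecule by
construction, their individual weights are not identifiable (only their
sum is); ground truth is therefore placed only on identifiable attributes.

What the generator does and does not emulate: it reproduces the *statistical*
shape of the problem — additive attribute contributions, noise, rare
attributes, prevalence imbalance between subsets (via
`perturb_subset_composition`) — but no chemistry.  Passing tests demonstrate
that the pipeline recovers planted additive structure under noise; they say
nothing about whether real toxicity is additive in SMILES fragments, nor
about performance on any experimental dataset.

`perturb_subset_composition` reorders records so that a chosen attribute's
bearers concentrate in the active-training block (the reordered list is cut
into consecutive A/P/C/V blocks by `assign_in_order`), creating known
nonzero d_k for end-to-end applicability-domain tests.

## Numerical choices and degenerate inputs

* Constant series (observed or descriptor) raise `UndefinedStatisticError`
  rather than returning NaN; during optimization such proposals are simply
  rejected.
* CCC of two identical constant series is 1 by convention.
* Leave-one-out R² values are clipped to [0, 1] to suppress rounding noise;
  a removal that leaves a constant series is treated as a tie with no
  protest.
* Ties in the supporter/opponent classification are exact float
  comparisons; for continuous data exact ties essentially never occur.
* The 311-record split produces subset sizes 79/77/78/77 (A/P/C/V): the
  n mod 4 surplus records cycle over the active-training and calibration
  sets, the two subsets that drive model building.
* Model files serialize floats with `repr`, so a reloaded model predicts
  bit-exactly.

## Problem sizes

The test suite and the acceptance script run the recovery experiment at
n = 400 molecules with three probes and three seeds, the adversarial-
calibration comparison at n = 400 with noise sd 1.0, and the domain
experiments at n = 200 with 2–5-token molecules.  These sizes give stable
statistics while keeping a full run in the low seconds on one CPU.

## Known limitations

* The IIC/CII/CCCP forms are reconstructions (see above); CCCP especially
  so.
* The tokenizer's multi-character table is an assumption; exotic SMILES
  (isotopes outside brackets, `@` without doubling, multi-digit ring
  closures beyond `%nn`) may tokenize differently than intended upstream.
* Attribute weights are only identifiable up to the usual collinearity
  caveats; interpretation of promoter roles inherits this.
* The applicability domain is exactly the statistical-defect rule — it does
  not detect novel chemistry expressed through common fragments.
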