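# Methods

This note documents the statistical procedures implemented in
`dropletomics`, the conventions chosen where the methodology left room,
what the synthetic-data generator does and does not emulate, and the
package's known limitations.

## Data model

An abundance table is a species × samples matrix with a units tag (`raw`
instrument signal, `permille_of_class`, or `permille_of_lipidome`), a class
annotation per species, and a sample → group design. *Not detected* (an
empty cell on disk, NaN in memory) is distinct from a detected zero: ‰
shares are computed over detected signal only, heat maps render undetected
entries grey, and multivariate models impute undetected as 0 (no signal)
at fitting time, with a log message.

The on-disk dialect is fixed (UTF-8 TSV, `#units=` comment line, columns
`species`, `class`, then samples; values printed with `%.17g` so
write→read round-trips are bit-exact). Published supplementary tables are
spreadsheet exports with varying layouts; mapping them into this dialect
is a one-time user step.

## Normalization and QC

**Class-relative**: `v'(i,s) = 1000·v(i,s)/Σ_{j∈class(i)} v(j,s)`.
No calibration is required because ionization efficiencies within a lipid
class are similar. The operation is idempotent and invariant to per-sample
uniform rescaling (instrument drift cancels).

**Lipidome-relative**: signals become molar amounts through internal
standards. Each class's calibration factor in a sample is the **median
over the class's standards of the per-standard molar response**
(spiked amount / measured signal) — a one-point robust calibration. With
one standard per class this is exactly `amount/signal`. Samples are then
normalized so the summed molar lipidome is 1000 ‰. The median across
responses (rather than across raw signals) is used because standards are
spiked at unequal amounts; for equal amounts the two are equivalent.
Retention-time-dependent response interpolation and isotope correction
are out of scope (they belong to upstream peak processing).

**Internal-standard QC**: for each standard the batch mean is computed
once over all samples; a sample is rejected when any standard deviates
strictly more than 30 % (configurable) from that mean. There is no
iterative re-meaning after rejection — the rule is a single
mean-then-reject pass, and a deviation of exactly 30 % is kept.

## Group profiling

Group profiles are arithmetic means and sample s.d. (n−1 denominator) over
the samples in which a species was detected. Fold-change matrices divide
each group mean by the across-group mean of the group means, computed over
the groups where the species was detected (undetected groups are excluded
from the reference rather than zero-filled, so a grey cell never drags the
reference down). Folds are clipped to [0.2, 5] for display; the unclipped
matrix is retained so the group means are recoverable up to the reference
scale.

The t test is the pooled-variance (equal-variance) two-sample test,
two-sided, with significance tiers at P < 0.05, 0.01, 0.001. Degenerate
zero-pooled-variance inputs: equal means give (t=0, p=1, ns); unequal
means are reported maximally significant with p printed as 0. No
multiple-testing correction is applied — tiers annotate profiles, they are
not a selection procedure here.

## Structural averaging

Within one class, the selection profile is the across-group mean of the
group mean profiles; the base peak is its most abundant species (=100 %),
and species at or above `threshold × base peak` (inclusive) are selected.
The abundance-weighted averages

    cl = Σ aᵢ·carbonsᵢ / Σ aᵢ        db = Σ aᵢ·double_bondsᵢ / Σ aᵢ

renormalize the weights over the selected subset, so subset averages are
well-defined even though subset totals are below 1000 ‰. Two computation
paths exist: per-group mean profiles (when only means are available), and
per-animal statistics summarized as mean ± s.d. with n = animals (the
default in the CLI). Raising the threshold can only shrink the selected
set (monotonicity, property-tested).

## PCA phenotyping

PCA is computed by SVD of the column-mean-centered samples × species
matrix — the covariance eigendecomposition without variance scaling, the
default behaviour of the standard R fitting routine (unit-variance scaling
is available behind a flag). Sign indeterminacy is fixed by making each
component's largest-|loading| element positive; published loadings are
therefore reproducible only up to a global per-component sign, and every
oriented quantity below is invariant to that flip (unit-tested).

Factor scores center with the training mean, `PC_x = Σ_i
(m_i−c_i)·l_{x,i}`, so a profile equal to the center scores 0 and training
samples reproduce their training scores. The discrimination contribution
between groups A and B on component x orients by the mean factor score:
the group scoring higher is "high", and

    ΔPC_x(i) = (mean_high(i) − mean_low(i)) · l_{x,i}

uses raw group means — centering cancels in the difference, which makes
the centered model and the raw-mean formula mutually consistent. By
linearity, `Σ_i ΔPC_x(i)` equals the oriented difference of group-mean
factor scores exactly; this conservation law is enforced at 1e-8 in the
tests. Contribution tables sort supporting (positive) species first; the
top-k cutoff (default 10) is a reporting parameter, not a claim.

Projection of an independent table applies the training center and
loadings with no refitting; classification assigns each projected sample
to the nearest training-group centroid (Euclidean, over the retained
components), reporting all distances and breaking exact ties by group-name
order with a warning. Refitting PCA on pooled training+projected data is
*not* expected to agree with projection and is deliberately not offered as
an equivalence.

## O-PLS-DA

Two classes are coded y = ±1 (alphabetically first group = +1, logged).
Preprocessing defaults to centering + unit-variance scaling — common
metabolomics practice, and required for the S-plot's correlation axis to
be comparable across species; center-only is available. Constant species
are left centered (all-zero) rather than scaled by a zero s.d.; they
surface in the S-plot with a missing correlation.

The algorithm is single-response orthogonal-signal-correction PLS:
`w ∝ X'y` normalized; per orthogonal round `p = X't/(t't)`,
`w_o ∝ p − (w'p)w` normalized, `t_o = Xw_o`, `p_o = X't_o/(t_o't_o)`,
`X ← X − t_o p_o'`; finally `t = X_filtered·w`. One orthogonal component
is the default for a two-class problem. Structural guarantees (tested):
each `t_o ⊥ t`; zero orthogonal rounds reduce to plain PLS; the Frobenius
variance splits exactly into filtered + removed parts; filtering never
lowers |corr(t, y)|.

S-plot axes: x = cov(t, xᵢ)/(n−1) against the unfiltered preprocessed
variables (the model loading on the original variable scale), y = Pearson
corr(t, xᵢ). Because the correlation relates the *filtered* score to the
*unfiltered* variable, even a perfect discriminator sits slightly below
|corr| = 1. The *weighted loading* is defined in this package as
`pᵢ·|corr(t, xᵢ)|` — the platform originally used for such analyses does
not document its formula, so this is an explicit package convention, and
the pieces (`p`, `corr`, `cov`) are all exposed for users who prefer
another weighting. Discriminant selection takes species with
corr ≥ +threshold (default 0.8) or ≤ −threshold whose |weighted loading|
reaches a quantile (default 0.9); subsets can be compared by refitting
PCA on each subset and measuring the two groups' centroid distance along
PC1 and PC1's share of the total between-centroid separation.

## Synthetic-data generator

The generator emulates the study conditions the pipeline targets: five
groups (WT-FED, WT-FAS, WT-HFD, KO-FED, KO-FAS) at n=3 (genetic-stress
arm) and n=6 (diet arm) by default; an even-carbon TG grid from 28:0 to
62:15 (138 species, double-bond cap growing with chain length) plus small
DG and PC panels; internal-standard rows (TG 17:0/17:0/17:0 at 40 nmol,
PC 12:0/12:0 at 1.2 nmol) with 5 % log-normal deviation and injectable
per-sample outliers for QC scenarios.

Per sample, `signal(i) = baseline(i) · group_factor(i) · exp(N(0, σ)) ·
sample_response`. The baseline is a smooth hump over (carbons, double
bonds) peaking near TG 52:2–52:3, normalized to a 1000 ‰ class profile.
σ = 0.25 on the log scale (multiplicative MS signal noise of realistic
magnitude); the per-sample response (σ = 0.10, around a 10⁶ raw-signal
scale) models instrument/loading drift and cancels under class-relative
normalization. Cells whose class-relative share falls below 0.2 ‰ become
not-detected, so missingness appears at the profile edges as in real
tables. A single integer seed drives one generator stream; identical
configs give byte-identical tables.

The preset plants three documented effect families, with fold magnitudes
chosen once to sit inside the 0.2–5× band that stress phenotypes display
in fold-change heat maps: fasting (both FAS groups) raises polyunsaturated
TG 52:4–58:x species 2–3× and halves two near-saturated abundant species;
high-fat diet raises TG 52:1/54:1/54:2/56:2 2.5–3×; combined
genetic+fasting stress raises very-long polyunsaturated TG (60:7–62:12)
4×; mild per-group chain-length/unsaturation log-slopes add global
trends. Ground truth (planted effects with directions per group pair,
noiseless class profiles, true base peak, noiseless cl/db averages) is
returned alongside the table.

What the generator does **not** emulate: correlated species (noise is
independent per species), retention-time or m/z structure, isotope
overlap, batch effects beyond a scalar response, molecular-species
composition underneath species, and real biological covariance between
classes. Recovery tests passing on synthetic data therefore demonstrate
the statistical machinery under the stated noise model, not performance
on any real lipidome.

## Problem sizes and numerical conventions

Recovery checks run the preset at n=10 per group over 50 seeds — large
enough for stable recovery rates, small enough that the whole suite runs
in seconds. Orthonormality, conservation and oracle-equivalence
tolerances are 1e-8 (1e-6 relative for Frobenius accounting); ‰ sums are
checked to 1e-6 relative. Ties: contribution ordering uses a stable sort
(input order preserved among equal values); centroid-distance ties break
by group name with a warning; an exact tie in group-mean factor scores
makes the ΔPC orientation undefined and raises an error rather than
guessing.

## Limitations

* Names are parsed, spectra are not: molecular-species identification,
  raw-file processing and peak integration are upstream concerns.
* The closed class set (TG, DG, PC, PE, PS, PI) is extensible at runtime
  (`register_class`), but oxidized/ether lipid notation and the full
  shorthand grammar are out of scope.
* Published per-study validation figures that require per-trial raw data
  (inter-study deviation percentages, accuracy/linearity of the LC-MS
  method) cannot be recomputed from species tables and are not attempted.
* Multi-class O-PLS-DA, cross-validated component selection (Q²) and
  permutation tests are not implemented; the O-PLS here is the two-class,
  fixed-component variant used for S-plot feature selection.
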