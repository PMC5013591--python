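# Methods

## Mass defect and the CHNO ceiling

For an observed m/z we define the mass defect as the fractional part
after the nominal (integer) mass, `defect(mz) = mz − floor(mz)`, always
in [0, 1). The floor convention (rather than rounding to the nearest
integer) is deliberate: it maps salt-cluster ions, whose exact masses sit
just *below* whole numbers, to defects near 0.9, i.e. *above* any CHNO
compound — a rounding convention would instead map them to small negative
offsets and break the one-sided threshold.

Among compounds restricted to C, H, N and O, the saturated alkane
C<sub>n</sub>H<sub>2n+2</sub> maximizes the defect at a given nominal
mass (hydrogen is the only element contributing a large positive defect
per nominal unit; N and O only lower it). We model the alkanes as
protonated ions [C<sub>n</sub>H<sub>2n+2</sub>+H]⁺, the form in which a
compound is actually observed in positive-mode electrospray. Over the
50–750 m/z working range this includes n = 4 … 53. Because
floor(m/z) = 14n + 3 throughout that range, the defects are *exactly*
affine in n, and an ordinary least-squares fit of defect on m/z is
essentially interpolation (R² > 0.9999):

```
defect = 0.0011166 · mz + 0.0195511      (full-precision element masses)
```

Rounded to five decimals this is slope 0.00112, intercept 0.01955. The
package's default operating line is the published form of this equation,

```
defect = 0.00112 · mz + 0.01953
```

which agrees with the refit to four decimals; the ~2 × 10⁻⁵ intercept
difference is far below any decision the filter makes (the smallest
feature-to-line margins in real data are ~10⁻²). Using the published
coefficients as the default keeps filter output byte-for-byte
reproducible against analyses run with that equation; `fit-model
--route alkanes` or the
`fit_threshold(alkane_series())` call switches to the refit line.

Element masses are monoisotopic NIST values via pyteomics (C exactly 12);
charged species subtract charge × electron mass (0.00055 Da). The
electron term is kept uniformly, including for adducts — it is below
every matching tolerance used but costs nothing to carry.

A second, data-driven route fits the same line through the upper
mass-defect envelope of a compound library: compounds are projected to
[M+H]⁺, those containing S, P or halogens are excluded (sulphates,
phosphates and iodinated hormones legitimately exceed the CHNO ceiling),
and the maximum-defect compound per 50-m/z bin is used for the fit. The
bin width is a package choice; the alkane route is the normative one and
the library route exists for users who want a line tailored to their own
library.

## The filter

Three nested rules, each a pure per-feature predicate:

1. **md** — remove when `defect(mz) > line(mz)`, *strictly*: a feature
   exactly on the line is kept (the line is a ceiling attained by real
   CHNO compounds).
2. **md + RT** — additionally require RT ≤ cutoff. On reverse-phase
   columns salt clusters elute in or shortly after the void volume while
   multiply charged peptides — the main genuine class above the line —
   are retained; the RT rule gives them back. The cutoff has **no
   default**: it is gradient-specific and should be set to the void time
   plus a margin.
3. **md + RT + inclusion** — finally, any feature matching an
   inclusion-list m/z within a ppm tolerance (default 5 ppm, matching in
   observed-m/z space) is kept regardless, protecting known high-defect
   endogenous compounds.

Every filter partitions its input (order preserved, no row duplicated or
dropped), is idempotent on its kept set, and the three stages are
monotone in leniency. Features outside the 50–750 m/z fit domain are
still filtered by extrapolating the line, with a warning.

The report object reproduces the standard four-row accounting (features
remaining and percent removed for none/md/md+RT/md+RT+inclusion),
with percent removed rounded to two decimals.

## Salt-cluster enumeration

Clusters are enumerated as charge-balanced combinations of Na⁺/K⁺ with
Cl⁻/HCOO⁻ (NH₄⁺ and acetate available, off by default), singly charged
by default, total units 2 … `max_units`, within the m/z window.
`max_units` defaults to **12**: beyond roughly a dozen Cl/K-heavy units
the accumulated per-unit defects (−0.031 per Cl, −0.036 per K) wrap the
total past the next nominal mass, producing mid-defect compositions
(e.g. [Cl₆K₇]⁺ at defect 0.559) that leave genuine salt-cluster space —
and such large aggregates are not what cluster series in plasma data look
like. At ≤ 12 units, 100 % of enumerated clusters in 50–750 m/z lie above
the default line in both polarities. Annotation matches observed m/z to
the nearest enumerated cluster within a ppm tolerance, breaking ties by
fewer units then lexicographic composition, so it is deterministic.

## Adducts and the library survey

An adduct definition maps a neutral mass M to
`(multimer · M + Σ delta ∓ charge · mₑ) / charge`. Defaults: [M+H]⁺,
[M+Na]⁺, [M+K]⁺, [M+NH₄]⁺ positive; [M−H]⁻, [M+Cl]⁻, [M+HCOO]⁻ negative;
registries are JSON-extensible since published adduct sets vary. The
survey counts a compound as "in cluster space" when *any* registered
adduct of the chosen polarity lands above the line inside the m/z window
(compound-level counting; per-adduct counting is available). Compounds
with no adduct inside the window are excluded from numerator and
denominator. Widening the registry can only grow the flagged fraction —
the mechanism is that compounds with near-integer masses wrap past the
next nominal mass under Na/K/Cl adducts.

## Synthetic data: what it emulates and what it does not

`synth.generate` draws labelled feature tables with four classes:

| class | defect | RT (min) | default counts (+ / −) |
|---|---|---|---|
| metabolite | uniform below 0.9 × line | 1.5–14 | 1730 / 1107 |
| cluster | real enumerated cluster m/z ± 2 ppm | 0.2–1.2 | 355 / 496 |
| peptide | above line (z = 2–3, M ~ 800–2100 Da) | 2–14 | 123 / 118 |
| inclusion-listed metabolite | above line + margin | 0.2–1.2 | 19 / 21 |

The plasma presets total 2227 (positive) and 1742 (negative) features and
encode the per-class structure implied by the published four-stage
accounting, so the filter's stage counts on preset tables reproduce that
accounting exactly — by construction of the class counts, not as an
independent measurement. Peptide m/z is rejection-sampled as
(M + z·proton)/z until it falls above the line inside the window, which
is the actual mechanism by which multiply charged peptides violate a
singly-charged ceiling (about half of z = 2 draws land above). RT
supports are a realistic C18 gradient choice (void ~0.5–1 min, 14-min
gradient); clusters and retained classes are disjoint by default with a
recommended cutoff at 1.35 min, and overlap is configurable to study
degradation. The generator does not simulate peak shapes, isotope
envelopes, intensity structure, in-source fragmentation, or
adduct-correlated feature groups — so perfect recovery on synthetic
tables demonstrates the *logic* of the filter, not its performance on
instruments whose RT structure violates the void-volume assumption.

`synth.synthetic_compound_library` emulates a metabolome mass library
for the survey: CHNO-like defects growing linearly with mass (rates
0.00012–0.00085 per Da) plus a 0.4 % high-defect sub-population standing
in for rare S/P/halogen chemistry. Survey percentages on it are
properties of this synthetic library, not of any real database; what
carries over is the ordering ([M+H]-only ≪ all-adduct, negative <
positive) and the order of magnitude.

## Numerical choices

- OLS via `numpy.linalg.lstsq`; verified in tests against explicit
  normal equations and `scipy.stats.linregress` to 1e-10.
- Strict `>` at the line; ties keep. ppm windows are two-sided and
  relative to the observed m/z.
- Reported coefficients round to 5 decimals; report percentages to 2.
- All randomness flows through one `numpy.random.default_rng(seed)` per
  generated object; no global state. Fixed seed ⇒ byte-identical output.
- Problem sizes used by the acceptance script: 50-point alkane series,
  110 clusters per polarity, plasma-scale tables (2227/1742 features),
  2000-compound survey library — all regenerate in seconds.

## Known limitations

- The RT rule assumes reverse-phase void-volume elution of clusters; on
  HILIC columns clusters elute late and the rule does not apply.
- Multiply charged *early-eluting* genuine compounds above the line
  would be removed unless inclusion-listed.
- The enumerator covers Na/K–Cl/formate (optionally NH₄/acetate)
  chemistry only; cluster series built from other buffer components
  need user-supplied building blocks.
- Doubly charged cluster ions are not enumerated by default
  (`charge_magnitude` is configurable); published annotated clusters are
  singly charged.
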