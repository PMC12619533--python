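# Methods

## Modified-cosine similarity and networking

Two MS² spectra are compared after weighting each fragment as
√intensity and L2-normalising the weight vector per spectrum. A fragment
pair (i, j) is eligible if |mzᵢ − mzⱼ| ≤ t or |mzᵢ − (mzⱼ + Δ)| ≤ t, where
Δ is the precursor mass difference and t the fragment tolerance (default
0.01 Da, suited to ~17 500 resolving-power MS²). The score is the maximum
total weight product over one-to-one pairings. We compute this exactly as a
maximum-weight bipartite assignment (`scipy.optimize.linear_sum_assignment`)
rather than by greedy product-descending selection: the assignment is
O(n³) in the peak count, negligible at MS² peak counts, and removes the
corner cases where greedy pairing is suboptimal. A pair eligible both
directly and shifted is counted once; `n_matched` counts assigned pairs
with positive product. Self-similarity is exactly 1.0 and the score is
symmetric in its arguments (the shift changes sign with argument order).

Candidate edges require score ≥ 0.6 and ≥ 6 matched ions. Each node ranks
its candidates by (score desc, matched ions desc, partner id asc) — the tie
rule is declared for determinism — and an edge is retained only when both
endpoints hold the other in their top 10. An optional maximum component
size iteratively removes the weakest edge of oversized components (off by
default). Subnetwork ids label connected components in descending size,
ties broken by smallest member feature id.

Precursor charge is assumed +1 throughout (positive-mode singly charged
lipid adducts).

## Annotation

A rulebook entry per lipid class (or sphingolipid subclass) declares the
adducts formed, a chain grid from which theoretical precursors are
enumerated via elemental formulas, and diagnostic evidence with weights.
For every candidate whose theoretical precursor matches the observed one
within 5 ppm, the score is the weighted fraction of evidence found within
0.01 Da among the fragment peaks; candidates with score ≥ 0.5 are ranked by
(score desc, |ppm| asc, name). The floor and the ranking are a declared
precision/recall knob.

Sphingolipid subclasses are separated by subclass-diagnostic neutral
losses: sulfate (97.9674 / 79.9568), sulfonate (81.9725, i.e. H₂SO₃ —
deliberately distinct from the sulfate losses), hexose (162.0528), the
protonated lysine-headgroup fragment (129.1022), a C28–C32 acyl loss
(1-O-acylCer), and the −15.9949 precursor family shift of the 1-deoxy
base. The decision sequence tests them in that order and falls through to
plain Cer. Sulfono/sulfate positions on the fatty acid chain are never
emitted — positional isomers are not resolvable from these spectra.

No per-class diagnostic fragment chemistry is asserted as literature-exact:
the default rulebook is generated from the same stylized fragment table
(`chem.CLASS_DIAGNOSTICS`) the spectrum simulator uses, so annotation logic
is exercised end-to-end against known truth. Real-data annotation would
replace this table with measured markers; the machinery is unchanged.

## Quantification

Single-point response factors: RF = mean(area/amount) over the injections
of a standard; a mix (e.g. the two-member ceramide mix, or the five-sterol
mix) contributes the mean of its members. Resolution order for a species:
exact subclass standard → class standard → configured proxy class (the
betaine RF stands in for glycolipids, the TAG RF for isoGDGTs, mirroring
the amino-lipid-proxy practice for classes without standards) → arithmetic
mean of all standards. The chosen source is recorded per species.

Per sample, amounts are corrected by the internal deuterated betaine
standard (DGTS-d9): amount = (area/RF) × (expected IS area / observed IS
area), with the expected IS area taken as the mean observed IS area across
samples — a scale-free choice since no nominal IS target is assumed.
Sterol-type signal is summed over [M+H]⁺, [M+NH₄]⁺, [M+Na]⁺ and
[M+H−H₂O]⁺ adduct features before calibration; features claiming the same
adduct of one species (unresolvable isomers or annotation ties) are kept as
separate rows with the best-scoring evidence under the canonical name.
Water concentrations divide by filtered volume (ng L⁻¹); sediment by dry
mass × TOC fraction (ng g⁻¹ TOC; dry mass defaults to 1 g per extract).
Values above 1000 ng are formatted as µg. Pigments are calibrated against
the chlorophyll-a standard measured as its pheophytin-a signal.
Quantification is linear in areas by construction.

## Composition

Class proportions are per-sample fractions of summed quantified lipids; a
class is lumped into "other" when its **median** fraction across samples is
below 1 % (the lumping scope — per sample or global — is genuinely open;
the median rule is the declared choice). The Hellinger transform is
√(cell/row-sum) with all-zero rows mapped to zero; PCA runs on the
column-centred matrix with each loading's largest-magnitude entry forced
positive for reproducibility. Presence uses a fraction-of-total threshold
of 0.02 % with the boundary **inclusive** (present at exactly 0.02 %);
zone-level presence is any-sample semantics. Intersection counts tabulate
species per exact group combination (UpSet cells); a plain count-summation
utility serves subclass totals.

## Synthetic data generator

The generator is first-class, tested code, not a fixture. Defaults encode
the study conditions:

- **Catalog.** Sphingolipid subclass counts 112/73/57/10/6/41/18
  (Cer/1-deoxyCer/1-O-acylCer/Gly-Cer/Lysine-Cer/Sulfono-Cer/Sulfate-Cer,
  317 total), chains uniform over base C15–C23 (0–1 unsaturations), fatty
  acid C14–C42 (0–2), extra 1-O-acyl chain C28–C32; odd and even FA carbon
  counts both occur (the bacterial odd-chain signature). 1-O-acylCer cores
  carry shorter amide chains (C14–C16). Non-sphingolipid classes: sterols,
  TAGs, PC/PE/PG/PI, betaine lipids, 1G-DEGs, isoGDGTs, C36–C40 alkenones,
  and a pheophytin-like pigment proxy.
- **Sample layout.** Six water depths (oxic 50 m, suboxic 90 m, euxinic
  500–2000 m) and nine sediment depths (three per phase: marine 5–96,
  transitional 96–136, lacustrine 136–211 cm below seafloor).
- **Zone targets.** Per-zone mean class fractions follow the basin's
  zonation: sterols ~63 % in oxic surface water, TAG maximum at the
  suboxic depth, phospholipids ~30 % and sphingolipids ~5 % in euxinic
  water, sphingolipids 15–28 % in sediments (9-sample mean ≈ 22 %),
  sediment phospholipids < 0.1 %. Targets are perturbed per sample by
  lognormal noise and renormalised.
- **Species structure.** Within-class species weights are one Dirichlet(1)
  draw per (class, matrix), so water and sediment communities differ in
  species makeup. Of the sphingolipid species, 69 % are sediment-exclusive
  and 9 % shared with the water column, reproducing the strong
  water/sediment partition of sphingolipid species.
- **Spectra.** Per species: the class diagnostics, the sphingoid-base
  fragment where applicable, and a six-peak CH₂-spaced co-fragment ladder
  whose intensity pattern shifts smoothly with total chain length, so
  chain-near homologs score higher — this gives subnetworks their
  chain-series structure. Every spectrum has ≥ 8 true peaks so the 6-ion
  rule is attainable. Spectra are deterministic per (seed, species,
  adduct).
- **Response distortion.** Hidden per-class RFs are lognormal around 100
  area/ng (log-sd 0.5); external-standard injection tables are emitted
  consistent with them, and sterol signal is split over the four adducts
  (0.65/0.20/0.10/0.05).
- **Noise defaults.** Class-fraction perturbation sd 0.05 (between-sample
  variability at the scale where zone structure stays interpretable);
  measurement-level area noise sd 0.01 (replicate-injection scale);
  fragment intensity jitter sd 0.25; fragment dropout 5 %; fragment m/z
  jitter sd 0.002 Da; precursor jitter sd 0.0005 Da; ~2 Poisson junk peaks
  per spectrum. `GeneratorConfig.noise_free()` zeroes all of them;
  `small()` gives a quarter-scale catalog for quick runs.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, co-elution interference, in-source fragmentation,
matrix effects, library-vs-rule annotation ambiguity on real fragmentation
chemistry, and within-class RF variation (equal response within a class is
assumed, as in the calibration model itself). Passing recovery tests
therefore demonstrate the correctness of the pipeline's logic under its own
assumptions, not annotation accuracy on real spectra.

## Numerical choices and degenerate inputs

- Duplicate fragment m/z within a spectrum are merged (intensity-summed)
  at 0.002 Da to avoid double-counting in cosine matching.
- Retention times are minutes internally; MGF `RTINSECONDS` converts on
  read. Feature alignment uses greedy single-linkage with 0.5 min RT and
  5 ppm m/z tolerances; multiple same-sample members of a group have their
  areas summed (gap-filling semantics); consensus m/z and RT are
  intensity-weighted means.
- Empty spectra are errors in similarity computation; empty MGF blocks are
  skipped with a warning; malformed blocks raise with the block index.
- All-zero samples are errors in proportion analysis (a sample with no
  quantified lipids has no composition).
- PCA requests beyond matrix rank are truncated with a warning.
- Quantification scale: test-suite and acceptance runs use the default
  catalog (317 sphingolipids + 67 other species, 15 samples, ~414
  spectra), which exercises every code path in a few seconds per stage.

## Acceptance measurement conventions

Quantification recovery is evaluated on species whose feature↔species
mapping is exactly correct in both directions — quantification accuracy is
defined for correctly identified analytes, and identification performance
is measured separately (top-1 class/subclass recovery, 100 % noise-free by
construction of the shared fragment model, ≥ 90 % under default noise).
Zone-proportion recovery compares unlumped class proportions with the
generator's targets.
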