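# Methods

## Mass conventions

All mass arithmetic uses a pinned monoisotopic table — H 1.00782503,
C 12 (exact), N 14.00307401, O 15.99491462, S 31.97207069, P 30.97376151 —
and integer mass numbers for nominal masses (C 12, H 1, N 14, O 16, S 32,
P 31). The table is deliberately pinned rather than pulled from a library:
sub-ppm errors on light sulfur ions move in the third decimal of the ppm
value when the sulfur mass changes in its eighth decimal, and this table
reproduces the reference diagnostic-ion errors (0.182 / 4.194 / 12.506 /
8.08 ppm for SO₃⁻, HSO₃⁻, SO₂⁻, HSO₂⁻) to the printed precision. A TSV
override hook exists for other instruments' conventions.

Two further conventions follow from the same reproduction requirement:

- **Anion m/z = monoisotopic mass of the atomic composition**, with no
  electron-mass term. An optional electron correction
  (`ion_mz(..., electron_correction=True)`, +m_e for a 1− anion) is
  provided but off by default; with it, the SO₃⁻ error would be ~7 ppm,
  not 0.182.
- **ppm errors use the theoretical mass as denominator**:
  (measured − theoretical)/theoretical × 10⁶. The measured-mass denominator
  differs in the fourth digit (visible at the 34.048 ppm level).

One known irreproducibility is documented rather than papered over: of the
five head-group fragment rows with printed mass errors, the three at
nominal m/z 136, 107 and 95 do not reproduce under *any* single convention
that reproduces the other five printed errors (recomputation gives 17.196,
55.97 and 20.9 ppm against printed 12.784, 51.31 and 16.737). They were
most likely computed against unprinted centroid masses. The package
reports its own recomputed values.

## Formula enumeration

`enumerate_formulas` searches element counts heavy-to-light with residual
mass-window pruning (fix S, P, O, N, C; bound H by what the window can
still absorb). The search is extensionally identical to exhaustive
enumeration — property-tested against a brute-force oracle on randomized
small bounds — and fast enough at fragment masses (≪ 1 ms at m/z 136 with
C0–100, H0–100, N0–100, O0–100, S0–4, P0–1 at 100 ppm). Default bounds
follow the conservative wide-window setting (100 ppm, C/H/N to 100, S ≤ 4,
P ≤ 1); oxygen, not explicitly bounded in the original constraint set, gets
the same 0–100 range as C/H/N since sulfonates require it. Candidates are
ranked by ascending |ppm|; ties break on fewer total atoms, then element
counts in C,H,N,O,P,S order (determinism, nothing more).

RDBE (C + 1 − H/2 + N/2 + P/2) is computed for every candidate but filters
nothing by default at the enumerator level.

## Head-group assignment and plausibility

`assign_head_group` delegates to the enumerator inside an m/z window, then
applies element requirements (N and S for an aminosulfonate head) and two
chemical-plausibility filters that formalize what is otherwise a manual
"most plausible formula" judgment:

- **Even-electron rule.** CID fragment anions are overwhelmingly
  closed-shell; for an ion composition evaluated without charge
  adjustment, a closed-shell anion has half-integer RDBE. The filter
  drops integer-RDBE (radical) compositions. At m/z 136.0045 this removes
  CH₄N₄O₂S (−7.3 ppm, a radical composition with four nitrogens) and
  leaves C₃H₆NO₃S (−17.2 ppm) as the top candidate — the aminopropane
  sulfonate head. The rule is deliberately *not* applied to the low-mass
  sulfonate diagnostics, where SO₃⁻ genuinely is a radical anion.
- **RDBE ≥ 0**: negative-RDBE compositions are not valence-realizable.

Both filters are keyword arguments and can be switched off; the raw
|ppm|-ranked list is then returned.

## Fragmentation model and structure hypotheses

Acyl species follow the standard two-acyl aminolipid fragmentation
chemistry: a fatty acid of chain length c, d double bonds and x ∈ {0,1}
hydroxyls leaves as the free acid C_cH_{2c−2d}O_{2+x}, as the ketene
(acid − H₂O), or appears directly as the carboxylate anion. The head
group, amide-linked to a 3-hydroxy acyl, appears after amide cleavage as
the doubly dehydrogenated, deprotonated ion (neutral head − 3H): for
aminopropane sulfonic acid C₃H₉NO₃S that is C₃H₆NO₃S⁻ at calc. m/z
136.0068. The carbonyl oxygen leaves with the acyl side, so the head
fragment keeps all three sulfonate oxygens.

Whole-lipid hypotheses combine a head-group candidate, an ester acyl
observed as a neutral loss, and an amide acyl searched over a library
(defaults c 10–22, d 0–3, x 0–1), under strict mass additivity
(total = head + acyl₁ + acyl₂ − 2 H₂O − H, checked to 10⁻⁶ Da). When an
isotope-labelling nitrogen count is available it is enforced against the
head group's nitrogen count. Hypotheses are ranked by |ppm vs precursor|;
ties (mass-degenerate acyl swaps such as 3-OH-16:0 + 18:1 vs
3-OH-17:1 + 17:0, which share a total formula) break on the supporting
loss peak's intensity and then its mass deviation — the fragment evidence
distinguishes what the precursor mass cannot. The 2- vs 3-amino positional
isomerism of the head group is carried as a flag and never resolved; MS
cannot place the amino group.

**Neutral-loss tolerance.** A neutral loss is the *difference* of two
measured m/z values, so its absolute error is governed by the heavier
ions, not by the loss mass: at 5 ppm per-peak accuracy, a 282 Da loss from
a 656 Da precursor carries ~13 ppm-of-loss error (1σ). Matching therefore
supports both a ppm-on-loss window (default 100 ppm, permissive by design:
observed fragment-level deviations reach ~50 ppm) and an absolute-Da
window; the structure round-trip uses the absolute form at
20 ppm × precursor. A 25 ppm strict mode is recommended wherever
candidates feed ranking rather than screening — the pipeline applies it to
head-group assignment, since wide-window stragglers at 40+ ppm only add
noise to hypothesis ranking.

The ~237.22 ion attributed to a 16:0 ketene is annotated at nominal mass
with an accuracy warning: the best ionic reading, [C₁₆H₃₀O − H]⁻, computes
to 237.2218, ~25 ppm from the observed 237.2159, and no composition within
20 ppm is satisfactory. The ¹⁵N count uses Δm(¹⁵N−¹⁴N) = 0.9970349 Da and
rounds the observed shift; the rounding residual is reported as a QC
number (the printed labelled precursor sits 1.8 mDa off one exact shift —
instrument deviation, not a second nitrogen).

## Strain screen

Relative abundance is SAL peak area over internal-standard peak area (a
di-17:0 phosphatidylglycerol standard in the motivating assay — metadata
only, no concentration conversion), optionally normalized to the cohort
maximum. The producer threshold defaults to 0.01 (ratio to IS): no numeric
limit of detection is published for the assay, so the value is config, is
logged, and the calls are monotone in it by construction. Phenotype calls
are condition-specific: a strain negative under one growth condition may
produce under another.

## Comparative genomics

The screen is strict presence/absence: core = OGs present in every
producer; producer-unique = core OGs absent from each non-producer
individually; candidates = producer-unique OGs whose representative
annotation (most frequent string per OG, ties lexicographic) matches a
case-insensitive keyword regex. The default pattern set is
`acyltransferase|acetyltransferase` — a plain "acyltransferase" would miss
GNAT-family acetyltransferases, which are plausible N-acyltransferases.
Soft frequency thresholds are deliberately absent; the reference screen's
logic is all-producers/no-non-producers, and the leaky-cohort check in the
test suite depends on that strictness. The screen operates on mapped
OG-assignment tables only; absence from the mapped table is not proof of
absence from the genome (close homologs below the orthology threshold are
known to exist in phenotype-negative strains).

The published table of 37 producer-unique candidate OGs ships as package
data (`salpipe/data/candidate_ogs.tsv`) for the funnel reproduction: the
keyword filter retains exactly 05CDD (SPO0716) and 08UX5 (SPO2471). The
upstream Venn counts (1417 core / 1060 shared) require the eleven real
genomes plus an orthology database and are out of scope; the screen's
correctness is instead established on synthetic cohorts with planted truth.

## Motif scanning and classification

Motifs are H-x(4)-D, H-x(5)-D and F-P-[ES]-G-[TV] over the 20-letter
alphabet, overlapping matches allowed, 1-based anchor positions (matching
His109/Asp115-style residue numbering). `X` in input data is tolerated at
wildcard positions but never satisfies a motif-specified residue.
Classification: a lone catalytic motif type decides (HX₅D → SalA-like,
HX₄D → PlsC/OlsA-like); when both occur, the type anchored by a
downstream FP[E/S]G[T/V] within 120 residues wins; otherwise
indeterminate. The 120-residue window is a stated approximation — the two
motifs co-occur in one alignment region in the reference enzymes but no
exact distance is published; it is configurable and logged. Alignment
input is tolerated (gaps stripped with a warning).

## Metagenome statistics

Gene abundance is normalized as 100 × abundance / median(10 single-copy
marker abundances) — approximately "percent of cells carrying the gene".
The marker set itself is configuration (ten named columns), not hard-coded,
since different surveys use different marker panels. Depth zones are
compared with the tie-corrected Kruskal–Wallis test (scipy) and Dunn's
post-hoc z tests, z_ij = (R̄_i − R̄_j)/√[(N(N+1)/12 − ΣT/(12(N−1)))(1/n_i +
1/n_j)] with ΣT = Σ(t³−t), two-sided normal p-values (sidedness is not
specified in the motivating analysis; two-sided is the conservative
default) and Holm's step-down correction via statsmodels. Normality
prefiltering (Shapiro–Wilk) is a pass-through flag: the tests used are
rank-based regardless. Zero gene abundances are retained as data.
Replicates are treated as per-sample observations.

## Synthetic data

Generators draw from per-generator named streams
(`default_rng([seed, stream_id])`), so outputs are byte-stable under a
fixed seed and adding a generator never shifts another's stream. Each
generator emits the ground truth needed to score its consuming stage.

- **Lipid spectra**: the default lipid is the SAL itself (homotaurine head,
  3-OH-16:0 amide, 18:1 ester). MS2 carries the ester-acid loss and the
  ester carboxylate; MS3 of the residual ion carries the head fragment and
  the four sulfonate diagnostics. All m/z values get Gaussian relative
  error (default σ = 5 ppm, typical Q-TOF fragment accuracy); decoy peaks
  are uniform over the spectrum range; intensities log-normal, with true
  fragments orders of magnitude above decoys as in real spectra.
- **Genomes**: background OGs are present per genome independently with
  p = 0.8 (core-set sizes of the right order for ~5000 background OGs
  across 9 genomes); one causal OG (all producers, no non-producer,
  acyltransferase annotation); confounders in both near-miss directions;
  and 36 clade-marker OGs (all producers, no non-producers, neutral
  annotations) emulating the phylogenetic signal of a real cohort — the
  reference funnel has 37 producer-unique OGs of which only one is the
  causal acyltransferase. Without clade markers, shuffled phenotype labels
  would be statistically exchangeable with true labels and the permutation
  control would be meaningless.
- **Proteins**: uniform residues with motifs overwritten at planned
  1-based positions; flanks are rejection-sampled so no accidental
  catalytic motif arises within ±10 residues of a plant. Accidental motifs
  elsewhere are expected (HX₄D arises per eligible window at (1/20)²) and
  are enumerated into the truth by an independent naive scan.
- **Abundance**: log-normal markers (μ = 2, σ = 1 on the log scale); gene
  abundance = median(markers) × 0.03 × zone effect × log-normal noise
  (σ = 0.5), putting the normalized percentage near 3% — the order of
  magnitude of a gene carried by a moderately abundant clade.

What the generators do *not* emulate — chromatography, isotope envelopes,
multiple charge states, correlated mass errors, real orthology-inference
noise, read-level sequencing — bounds what green tests show: they
establish the correctness and calibration of the *computational chain*,
not instrument- or database-level robustness.

## Numerical and degenerate-input choices

- Enumerator windows use a 10⁻¹² relative guard on ceil/floor boundaries.
- Complete-tie groups return H = 0, p = 1 (scipy raises instead).
- All-zero screening cohorts return zeros with a warning; a failed
  internal standard (area ≤ 0) is an error, not a zero.
- Empty non-producer sets make producer-unique = core, with a warning.
- Report writers print m/z to 4 decimals and ppm to 3, with sorted keys,
  so identical inputs give byte-identical reports.

## Validation summary

The test suite establishes: enumerator ≡ brute force (randomized bounds);
scanner ≡ naive position scan (1000 random sequences); printed-value
reproduction for every mass error above; structure round-trip top-1
recovery ≥ 95% over 200 noisy replicates (measured 99–100%); ¹⁵N count
recovery 100/100; planted-OG recovery 50/50 cohorts, 0/20 with a leaky
non-producer; Kruskal–Wallis type-I rate within [0.03, 0.07] over 2000
null simulations; Dunn/Holm power ≥ 95% against a 5σ shift. Problem sizes
(200 spectra, 50 cohorts of 1000 background OGs, 2000 null simulations)
keep the full suite around a minute on one CPU while leaving binomial
noise on the measured rates well inside the asserted margins.

## Known limitations

- Single deprotonation only; no adduct chemistry, no |z| > 1, no
  positive-mode fragmentation.
- The even-electron head-group filter is a heuristic; genuinely radical
  head fragments would be filtered out (disable the flag in that case).
- Motif classification by regex spacing cannot see structural adjacency;
  divergent sequences with unusual motif spacing need the window widened
  or manual review.
- The comparative screen inherits the orthology mapping's blind spots
  (pseudogenes, below-threshold homologs).
- Real-survey quantities (global abundance percentages, taxonomy
  fractions of real homolog sets) require external datasets and are
  outside the package's scope; `taxonomy_fraction` implements the
  arithmetic only.
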