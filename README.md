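# salpipe

Discovery pipeline for **sulfur-containing aminolipids (SALs)** — a class of
bacterial membrane lipids built from an aminopropane sulfonic acid head
group amide-linked to a 3-hydroxy fatty acid, which is esterified to a
second fatty acid. SALs are made by marine roseobacters
(*Rhodobacteraceae*), where their synthesis depends on *salA*, a
lysophosphatidic acid acyltransferase (LPAAT) family gene distinguished
from PlsC/OlsA by an extended HX₅D catalytic motif.

The package implements, as reusable library code, the computational chain
by which such a lipid and its biosynthesis gene are identified:

1. **Formula assignment** (`salpipe.formula`) — bounded CHNOPS enumeration
   of elemental formulas for an accurate mass under a ppm tolerance, with
   monoisotopic/nominal mass arithmetic, signed ppm errors
   (ppm = (m_obs − m_theo)/m_theo × 10⁶) and ring-plus-double-bond
   equivalents (RDBE = C + 1 − H/2 + N/2 + P/2).
2. **MSⁿ annotation** (`salpipe.annotate`) — lock-mass correction,
   fatty-acyl neutral-loss matching (free acid C_cH_{2c−2d}O_{2+x}, ketene,
   carboxylate anion), diagnostic sulfonate ions (SO₃⁻/HSO₃⁻/SO₂⁻/HSO₂⁻),
   head-group assignment, fragmentation trees, ¹⁵N-label nitrogen counting,
   and ranked whole-lipid structure hypotheses under the mass-additivity
   constraint M([M−H]⁻) = M(head) + M(acyl₁) + M(acyl₂) − 2·M(H₂O) − M(H).
3. **Strain screen** (`salpipe.screen`) — SAL peak areas relative to a
   phosphatidylglycerol internal standard; producer/non-producer calls.
4. **Comparative genomics** (`salpipe.compgen`) — orthologous-group (OG)
   presence/absence screen: OGs present in *all* producer genomes and
   absent from *every* non-producer genome, filtered by annotation keywords
   (acyltransferase/acetyltransferase) to nominate candidate genes.
5. **Motif classification** (`salpipe.motifs`) — HX₄D/HX₅D catalytic and
   FP[E/S]G[T/V] substrate-binding motif scanning; SalA-like vs
   PlsC/OlsA-like calls.
6. **Metagenome statistics** (`salpipe.metag`) — gene abundance as a
   percentage of the median of ten single-copy marker genes; depth-zone
   comparison with Kruskal–Wallis plus Dunn's post-hoc under Holm's
   correction.
7. **Synthetic data** (`salpipe.simulate`) — seeded generators for every
   stage's inputs with ground-truth bookkeeping, and statistical validation
   harnesses (`salpipe.validate`) built on them.

The numbered scripts under `analysis/` run the stages in discovery order
and write their tables to `results/`; `salpipe` is also a command-line tool
(`formula-assign`, `annotate-ms`, `label-shift`, `lipid-screen`,
`compgen-screen`, `motif-scan`, `meta-abund`, `simulate`, `run-all`).

## Worked example

Annotating the fragment evidence for the SAL precursor at m/z 656.4882
(`python analysis/01_lipid_evidence.py`):

```
Sulfonate signature: present (4/4 diagnostic ions)
    ion  measured_mz  theoretical_mz  abs_ppm
    SO3      79.9568         79.9568    0.182
   HSO3      80.9643         80.9646    4.194
    SO2      63.9611         63.9619   12.506
   HSO2      64.9692         64.9697    8.080
C3H4SO3     119.9922        119.9881   34.048

Head-group candidates at m/z 136.0045 (plausible, N+S, 25 ppm):
  C3H6NO3S      -17.196 ppm
Neutral loss at 374.2364: 18:1 free acid (-14.5 ppm of loss)
15N labelling: shift 656.4951 -> 657.4903 counts 1 nitrogen (residual -1.8 mDa)

Top structure hypothesis: head C3H9NO3S (aminopropane sulfonic acid, isomer
position ambiguous), amide 3-OH-16:0 free acid, ester 18:1 free acid ->
[M-H]- C37H70NO6S at 656.4924 (-6.4 ppm vs measured)
```

Reading the numbers: all four low-mass sulfonate fragment ions are present
within tolerance (sub-ppm for SO₃⁻), establishing a sulfonate group; the
m/z 136.0045 ion is assigned C₃H₆NO₃S⁻, the dehydrogenated deprotonated
aminopropane sulfonic acid head group (2- vs 3-amino positional isomers are
indistinguishable by MS); the dominant MS² loss of 282.25 Da is an 18:1
fatty acid; the one-dalton ¹⁵N shift counts exactly one nitrogen; and the
only structure consistent with all of it is the two-acyl aminosulfonate
lipid C₃₇H₇₀NO₆S⁻ ([M−H]⁻ calc. 656.4924).

The comparative-genomics stage (`python analysis/03_comparative_genomics.py`)
filters the 37 orthologous groups unique to SAL-producing strains down to
the two annotated acyltransferases, 05CDD (locus SPO0716, *salA*) and
08UX5 (SPO2471), and demonstrates on synthetic cohorts that the screen
recovers a planted causal OG while label permutations collapse the
producer-unique set.

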