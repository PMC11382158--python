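# Methods

This note documents the models, conventions and defaults behind the `aho`
pipeline, the design choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Record model and normalization

A reaction record carries substrate/product/ligand SMILES, the catalyst
metal, solvent, pressure (atm), temperature (°C), catalyst loading (mol%),
and outcomes (%ee, yield, conversion, each in [0,100]). %ee is stored as a
magnitude; the enantiomer sign is out of scope because the analysis works
in selectivity regimes, not configurations.

Normalization conventions:

- Solvent synonyms, abbreviations and SMILES map to one canonical label via
  an editable YAML table (`aho/data/solvents.yaml`); unknown labels pass
  through unchanged rather than being guessed.
- "rt"/"room temperature" normalizes to 25 °C — a single declared
  convention, since sources disagree by a degree or two either way.
- Pressure accepts atm, bar and psi (1 bar = 0.98692 atm, 1 psi = 0.068046
  atm). Unit unification is mandatory before any binning of literal values.
- Multi-fragment SMILES are reduced to the largest organic fragment
  (counterion/solvate stripping), except when Fe is present: ferrocene
  sandwiches are usually written as disconnected fragments and the
  classifier must see the whole set.
- Validation failures quarantine the row with a machine-readable reason;
  quarantined + accepted always equals input rows.

Metal extraction scans the catalyst string for d-block element symbols; a
string with zero or several distinct transition metals is an error rather
than a guess. Structure identity uses RDKit canonical SMILES;
stereoisomers count as distinct structures by default (a flag collapses
them), since the convention used by published "distinct olefin" counts is
not stated anywhere we could verify.

## Reacting-alkene perception

Candidate sites are all non-aromatic C=C bonds; carbonyls/imines, aromatic
bonds and cumulated (allene) units are excluded, ring alkenes are eligible.
Substitution degree is the count of non-hydrogen neighbors of the two
alkene carbons (1–4 → mono- to tetrasubstituted). Monosubstituted alkenes
are perceived and reported in their own bucket even though the di/tri/tetra
taxonomy downstream does not use them.

When a product is available, the reacting bond is the unique candidate
whose saturation reproduces the product graph; the comparison strips
stereochemistry because the reduction creates new stereocenters. Without a
product, a single candidate is returned as-is; among several, the site
matching the most specific functional class wins (tie: lowest canonical
atom rank) and the result is flagged ambiguous. This priority rule is a
declared convention for polyenes, not an inference about how any published
count handled them.

## Olefin classification

Six classes are evaluated strictly relative to the reacting C=C, from a
versioned SMARTS rule pack (`aho/rules/olefin_rules.smarts`) whose patterns
are anchored at the two vinylic carbons via atom maps:

- enamide/enamine: N on a vinylic carbon (enamide when acylated);
- enol: O on a vinylic carbon, subtyped ester/carbamate/phosphinate/
  phosphonate/silyl/ether by the group on that O;
- α,β-unsaturated carbonyl: vinylic carbon bonded to a carbonyl carbon
  (acid/ester/amide/ketone/aldehyde subtypes);
- other-heteroatom: any non-C/H/O/N atom (F, Si, B, P, Cl, ...) on a
  vinylic carbon;
- allylic alcohol/ether: O on an sp3 carbon adjacent to the alkene, unless
  that O itself sits on a vinylic carbon (then the enol rules own it);
- aryl/alkyl: only C/H at the vinylic positions; also the fallback, so the
  class set is never empty.

Classification is multi-label (dehydroamino esters are enamide + conjugated
ester at once). The primary class follows the fixed precedence

    enamide/enamine > enol > other-heteroatom > α,β-unsaturated carbonyl
    > allylic alcohol/ether > aryl/alkyl

chosen so that dehydroamino-acid derivatives count as enamides and
fluorinated conjugated acids count as heteroatom-bearing alkenes. Any
precedence is a convention: per-molecule class assignments behind published
aggregate percentages are not available, so exact percentage reproduction
is not a meaningful target for multi-functional substrates — the pipeline
exposes the full class set precisely so users can re-aggregate under a
different convention.

## Ligand classification

Donor perception covers: trivalent P, subtyped by its neighbor pattern (3C
phosphine; 1O phosphinite; 2O phosphonite; 3O phosphite; 2O+1N
phosphoramidite; N without O aminophosphine); P=O phosphine oxide (treated
as a donor class because ligand taxonomies list it, not because P(V)
coordination resembles P(III)); sp2 nitrogen (oxazoline, pyridine,
thiazole, imidazole, imine); classical NHC carbenes (divalent C between two
ring N in a 5-ring); and thioether S / ether O. Amide and nitro N are never
donors. S/O donors are admitted only when they complete a P,S / P,O
chelate — a trivalent P in the window below with no N, carbene or second P
partner of its own — so an oxazoline ring O or an ester O never inflates
denticity.

Denticity is operational: donors pairwise 2–6 bonds apart through the
ligand skeleton form a chelate; the largest such clique labels the ligand
(ties prefer P,N over P,P over the rest). The window is a declared
heuristic that reproduces conventional assignments for
phosphine-oxazolines, diphosphines (dppe- and BINAP-type),
bis(imino)pyridines and Josiphos-type ferrocenyl diphosphines; donors
farther apart count as independent monodentate sites.

Ferrocene detection requires the full sandwich — an Fe atom plus two
all-carbon five-membered (aromatic or anionic) rings — not merely an Fe
atom. Ferrocene-based ligands keep their donor classification and get
their own "ferrocenyl ..." reporting bucket by default (a flag merges them
back into the donor-based buckets, since published ligand-type shares do
not state which convention they used).

Known limitation: chelates whose donors sit on *different* cp rings
(dppf-style) appear as disconnected fragments in SMILES, so no through-bond
path exists and they classify as monodentate. The shipped templates use
Josiphos-type connectivity (both donors reachable through one fragment),
which is also the dominant ferrocenyl motif in asymmetric hydrogenation.

## Aggregation

- %ee regimes use right-closed bins with default edges 70/80/90/95/99 —
  the edges behind published regime plots are not stated, so they ship as
  config, not as a hardcoded truth.
- Distributions are computed per metal with optional top-N truncation and
  an explicit "other" remainder; records lacking the grouped value are
  excluded and counted.
- Combination matrices hold one cell per observed (degree, olefin class,
  ligand category) with the exact sample median %ee (mean-of-middle-two for
  even n); unobserved combinations are absent by construction and derived
  downstream as empty cells. Cell counts always sum to the classified
  total per metal (a tested conservation law).
- Top-N structure rankings break count ties by lexicographic canonical
  SMILES, making every ranking deterministic.
- Reported denominators are reactions, not distinct substrates (a flag
  switches); whether published percentages used one or the other is not
  stated.

## Chemical space

Structures are deduplicated by canonical SMILES and fingerprinted with the
standard 166-bit MACCS key set. Embeddings (UMAP default: 15 neighbors,
min_dist 0.1; t-SNE: perplexity 30, PCA init) are pure functions of
(distinct fingerprints, method, seed) and are *qualitative*: no published
hyperparameters exist, so coordinates are not expected to match any
published picture numerically — only cluster/overlap structure is in
scope. Structures used with several metals get a "shared:<metals>" group
label. Overlap tables are plain set intersections of per-metal canonical
structure sets; mean-%ee coloring is the arithmetic mean over all
reactions of a structure, with structures lacking ee excluded and counted.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested:

- metal shares Rh 0.531 / Ir 0.379 / Co 0.01 / Ru 0.08;
- per-metal joint (degree, class) mixes: trisubstituted mass 0.62 (Ir) /
  0.61 (Rh) with near-even di/tri for Co; Ir dominated by aryl/alkyl
  alkenes, Rh by unsaturated carbonyls (disubstituted) and
  enamides/enamines (tri/tetrasubstituted), Co mixing both, tetrasubstituted
  Co almost entirely unsaturated acids;
- per-metal ligand mixes: bidentate P,N mass 0.85 for Ir (phosphine- and
  analogue-oxazolines, phosphine-pyridine/imine, ferrocenyl P,N);
  phosphoramidite 0.21 / bisphosphine 0.27 / ferrocenyl bisphosphine 0.23
  for Rh; bisphosphine-heavy Co with 0.28 bis(imino)pyridine;
- conditions: DCM 0.80 and 49–50 atm 0.63 for Ir; DCM 0.42 and sub-50-atm
  pressures for Rh; toluene/alcohols, warmer temperatures and mixed
  pressures for Co; room temperature mass 0.72 for Ir/Rh and 0.30 for Co;
- %ee: mixture 0.6·(100 − Exp(mean 4 %), truncated to [0,100]) +
  0.4·U(20,100) — a heavy mode near 100% ee over a broad background. The
  exact published shape is unavailable; this mixture reproduces its
  qualitative skew without claiming more. A per-structure normal mode
  exists for tests that plant known structure-level means.

Every record is assembled from a template library: ≥2 olefin scaffolds per
(degree, class) cell and ≥2 ligands per category, each verified by the
package's own classifiers at test time (self-consistency gate). Scaffolds
are optionally decorated at aromatic CH positions ≥4 bonds from the alkene,
from the closed alphabet {Me, Et, Ph, OMe, F}, so decoration provably
cannot change the planted class. The product is formed by saturating
exactly the planted C=C; the truth table stores an atom-mapped substrate so
site recovery can be checked index-free. Generation is a pure function of
the config (fixed seed → byte-identical output).

What passing tests therefore show: the pipeline's perception, classifiers,
aggregation and bookkeeping are exact and invariant on in-distribution
molecules whose ground truth is known. What they do not show: performance
on real literature structures — the generator does not emulate exotic
scaffolds, misdrawn SMILES, tautomers, dppf-style cross-ring chelates, or
any correlation between structure and conditions beyond the configured
per-metal models; and synthetic per-metal structure overlaps are far higher
than in real data because all metals draw from one template library.

## Numerical and testing choices

- All randomness flows through one integer seed per run
  (`numpy.random.default_rng`); categorical sampling sorts category keys so
  dict insertion order never affects output.
- Degenerate inputs are contracts, not crashes: empty record sets give
  empty reports; a substrate without any alkene is excluded with a reason;
  a ligand without donors classifies as denticity "other"/"none".
- Problem sizes used by the test suite and the acceptance script — 10,000
  reactions for recovery and share checks, 1,000 atom permutations for
  invariance, 20 seeds for the metal-share and embedding-separation
  checks, 100 random set triples for overlap verification — were chosen to
  make binomial noise small relative to the margins being tested while
  keeping a full run in the minutes range on one CPU.
- Stochastic shares are tested statistically: two-sided binomial CIs for
  "equals p" claims, one-sided tests for "exceeds p" claims, and 19/20-seed
  pass criteria where a per-seed fluke is expected.
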