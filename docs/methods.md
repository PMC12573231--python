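# Methods

## Mass model

All masses are assembled from elemental formulas — signed multisets of
(element, optional isotope) counts — using an embedded monoisotopic atomic
mass table (IUPAC/AME values, ≥ 9 decimals). Signed counts make loss and
linker chemistry first-class: the disulfide bridge is the formula H₋₂, the
phospho neutral loss H₃O₄P. Fragment m/z is (neutral + z·m_proton)/z with
m_proton = 1.00727646677 Da. Only monoisotopic matching is supported;
average masses and isotope-envelope prediction are out of scope, so the
heavier isotopologues of matched fragments remain unannotated by design.

Numeric modifications written as `[+mass]` carry no formula; fragments
containing them track a separate scalar term, and such modifications
contribute no neutral losses or diagnostic ions.

Global isotope substitution (`<15N>`, `<13C>`, `<D>`) rewrites the plain
element keys of every formula of the affected peptidoform — residues,
modifications, and loss formulas alike — immediately before mass
evaluation. This matches fully labelled material; partially labelled
modifications are not modelled separately.

## Peptidoform model

ProForma 2.0 text is tokenized by `pyteomics.proforma` and converted into
the package's own model. The supported subset is: residue modifications by
registry name, accession alias or bare mass; `[Glycan:composition]` and
`[GNO:id]` (the latter resolved against a user topology file); terminal,
labile (`{...}`) and unknown-position (`[...]?`) modifications; `#XL`
cross-link pairs; `+`-separated chimeras; `/z` charge; global isotope
substitution. Anything else (tagged intervals, fixed-modification
prefixes, non-proton adducts, ambiguity groups) raises a named
unsupported-feature error rather than parsing partially.

Ambiguous residues: J is mass-equivalent to L/I; B and Z expand to two
mass alternatives (N|D, Q|E) that propagate through fragment generation as
tagged variants; X is accepted only with an explicit mass modification.
Unknown-position modifications always count toward the precursor mass and
appear on backbone fragments only as optional variants; in the statistics
a peak is counted once regardless of how many placement variants match it.
Mass variants per position are capped at 512; exceeding the cap raises an
error rather than exhausting memory.

## Fragment generation

Backbone conventions (prefix_i includes residues 1..i with located mods
and N-terminal mods; suffix_j the C-terminal j residues, mods, and H₂O):
a = prefix − CO, b = prefix, c = prefix + NH₃, x = suffix + CO − H₂,
y = suffix, z = suffix − NH₃, with per-series hydrogen-offset variants
(z• = z + H is the default in electron-based presets). Full-length b_n/y_n
are not emitted; the intact species appears only as the precursor, which
avoids double counting in the statistics.

Satellite hydrogen bookkeeping, chosen for internal consistency and
oracle-tested by formula arithmetic: d_i = a_i + H − distal(residue i)
(the a+1 radical loses the Cβ distal group as a radical); w_j = z•_j −
distal; v_j = y_j − sidechain + H (the complete side chain replaced by H,
making v of leucine the glycine-equivalent y ion at m/z 76.0393). The
default distal-group table covers V (CH₃), I (CH₃, C₂H₅ — two d/w
variants 14.0157 Da apart, the Leu/Ile discriminator), L (C₃H₇) and
T (CH₃, OH); satellites are generated only for the residue adjacent to
the cleavage.

Neutral losses pool three sources per fragment: the series' configured
losses, losses of modifications inside the fragment stretch (e.g.
−H₃O₄P for phospho, −CH₄OS for oxidized Met), and the model's per-residue
side-chain losses. Combinations up to a per-series maximum (default 1
simultaneous loss) are emitted. Charges default to 1..precursor charge
per series and for precursors, which also covers matching of deconvoluted
(decharged) data read as singly charged peak lists.

### Glycans

Composition glycans enumerate every distinct sub-multiset within the
configured size bounds: B candidates are the non-empty sub-multisets,
Y candidates retain each sub-multiset on the intact peptide (including the
empty set, Y0, and the full composition). Topology glycans enumerate every
connected subgraph of the rooted tree: root-containing subsets give Y ions
(peptide + retained nodes), the others B ions, each annotated with its
broken bonds; the full tree detached at the root attachment is also
emitted as a B ion (the full-glycan oxonium — the complement of Y0), so a
single-HexNAc topology still yields the canonical 204.0867 oxonium.
Internal oxonium ions are simply B fragments with more than one broken
bond; no separate kind exists. Glycosidic breaks transfer no hydrogen
(B = Σ residues, protonation gives the oxocarbenium), which reproduces
204.0867 for HexNAc exactly and makes every single-break B/Y pair sum to
the intact glycopeptide mass.

Glycans ride intact on backbone fragments (electron-based behaviour);
glycan cleavage is combined only with the intact peptide (the Y series).
Labile glycans produce B/oxonium ions and precursor-level Y ions but are
excluded from backbone fragment masses. Oxonium diagnostic ions have
per-monosaccharide defaults (HexNAc: −H₂O, −2H₂O, −C₂H₄O₂, −C₂H₆O₃;
Hex: −H₂O, −2H₂O; NeuAc: −H₂O), all user-overridable.

### Cross-links

A cross-link is a linker-capable modification referenced at exactly two
sites. A backbone fragment spanning one endpoint carries, as variants:
the intact link (linker delta plus the full mass of everything attached
through it, walking transitively across chains) and one variant per
breakage rule, adding only the rule's retained delta. Breakage deltas are
relative to the unmodified residues. Of the three disulfide rules, the
S-transfer rule (H₋₂S₋₁:S₁) conserves the linker delta H₋₂ exactly; the
other two differ from it by one and two hydrogen atoms — hydrogen uptake
upon electron-based cleavage — so only the S-transfer rule yields strictly
mass-conserving complementary pairs, and the test suite asserts exactly
that structure.

Cleavage positions whose two backbone sides remain connected through
intact links (loops within one chain, or multiply-linked chain pairs) are
cyclic: no intact fragment exists there, and fragments are emitted only
for variants in which a spanning link is broken. Non-cleavable linkers
therefore suppress backbone fragments inside their loop entirely, while
precursor and diagnostic ions are unaffected.

## Matching and statistics

Each theoretical fragment is assigned the nearest peak within the
tolerance (ppm or Th); several fragments may share a peak and no
post-filtering is applied. Equidistant peaks tie-break toward lower m/z,
deterministically. Matching is binary-search based and verified against a
brute-force O(n·m) oracle.

The four statistics use the noise-filtered spectrum as the universe (the
filter defines what matching ever sees): peaks annotated = matched
peaks / peaks; intensity annotated = matched intensity / total intensity;
fragments found = distinct matched / distinct generated fragments, where
distinct means the (kind, peptidoform, position, variant, losses, charge)
tuple — charge states count separately; sequence coverage marks residue i
covered if a matched N-terminal-series fragment has index i or a matched
C-terminal-series fragment has index n − i + 1, satellites following
their parent series. Chimeric spectra report per-member statistics plus a
pooled total; coverage is only reported per member.

The default noise filter interprets the value 1.0 as an absolute intensity
floor (the unit of that convention is ambiguous in common practice; the
semantics are explicit and configurable: absolute or relative-to-base-peak
percent).

## False match rate

The spectrum is shifted by π + k Th for k = −25..24 — exactly 50 offsets
straddling ±25 Th, the irrational π guarding against isotope-pattern
re-matching on integer shifts — and each shifted spectrum is re-matched
against the same fragment list. The FMR pair is the mean matched-peak
count and mean matched intensity over the offsets divided by the
unshifted values. It is undefined (a raised signal, never 0) when the
unshifted annotation matches nothing. Values above 1 are possible only
for adversarial spectra; no ceiling is enforced.

## Fragmentation model presets

Presets are inspired by common practice and fully user-overridable (every
model serializes to JSON): `cid_hcd` (a/b/y + H₂O/NH₃ losses, immonium,
diagnostics, glycan fragmentation), `etd` (c/z• + NH₃), `ethcd`/`etcad`
(b/c/y/z• + H₂O/NH₃ and the electron-type losses CHO₂ and C₂H₃O₂,
immonium, glycans), `ead`/`eacid` (a/b/c/y/z•/d/w + glycans + oxonium),
`uvpd` (all nine series), `bare` (b/c/y/z, no losses), `all`. The exact
loss sets and charge rules of any given instrument method vary; these
defaults are starting points, not measurements.

## Synthetic data

The generator builds a spectrum directly from a peptidoform's theoretical
fragments: a chosen fraction of the distinct fragment m/z values becomes
peaks with log-uniform intensities (default 10³–10⁵), Gaussian m/z jitter
in ppm, plus uniform random noise peaks. All randomness flows through one
seeded generator; fixed parameters give byte-identical mgf output. It
emulates peak positions and densities, not fragmentation physics: no
intensity structure by ion type, no isotope envelopes, no correlated
noise. Passing round-trip tests therefore demonstrates bookkeeping
correctness (generation ↔ matching ↔ statistics), not annotation accuracy
on real instrument data. Default test conditions: full fragment
realization at zero jitter for exactness checks, 5 ppm jitter against the
20 ppm default tolerance for robustness checks, problem sizes of 8–15
residues and batches of ≤ 10 PSMs, chosen to keep the full suite within
seconds while exercising every code path.

## Known limitations

- No internal (non-immonium) backbone fragments; no cyclic peptides.
- No vendor raw formats (Thermo RAW, Bruker TDF) — convert to mzML.
- The bundled modification registry is minimal (8 definitions); everything
  else comes from user JSON files. Full PSI-MOD/UNIMOD/GNOme/XLmod/RESID
  ingestion is out of scope.
- `[GNO:id]` requires a user-supplied id → topology file; there is no
  built-in structure database.
- USI strings are parsed but never fetched from the network by this build.
- Intensity prediction and database-search scoring are non-goals.
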