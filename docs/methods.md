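# Methods

This note documents the models and procedures `foramforge` implements,
the defaults it ships, and what its synthetic-truth tests do and do not
demonstrate about real data.

## Record schema and ingestion

The unit of observation is one species at one sample depth in one drill
hole.  The output schema carries the species name in both original
(`orig.species`) and senior-synonym (`species`) form, the abundance in
original (`orig.abundance`) and numeric (`abundance`) form with its unit
class (`abun.units`), the per-sample specimen totals (`total.IDd`,
`num.ind`) and relative percent abundance (`rel.abun`), the full set of
age-model outputs, modern and paleo-coordinates, drilling metadata, and
the `trim` QC flag.  Absent values serialize as `NA`.

Ingestion is driven by one column-mapping config per source (YAML)
instead of per-source scripts, so a new source is added by writing a
mapping, not code.  Wide (samples × species) tables are melted to long
form, one record per non-empty cell.  Identifiers are assigned after a
deterministic sort on (`holeID`, `sample.depth`, `species`): `holeID`
embeds the source so the same site label arriving from two sources stays
distinct; `sampleID` is the hole plus a sample ordinal; `rowID` is
`db.ID:sampleID:row-ordinal`.  Re-running on identical input reproduces
identical IDs; a collision aborts, since it would indicate
non-deterministic ordering.

Records missing any of the four crucial columns — species name, numeric
abundance, age, paleocoordinates — are removed at the end of the
pipeline, each with exactly one primary reason (checked in that order) so
the validation report partitions the input.

## Taxonomy

Synonym resolution is table-driven: each raw name maps to one senior name
with a status (`valid`, `junior synonym`, `typo`, `invalid`,
`Mesozoic-only`, `not-species-level`).  Typos are required to be listed
explicitly — no fuzzy matching is attempted, because silent fuzzy
corrections are harder to audit than an explicit curation log.  Names
carrying open-nomenclature qualifiers (`cf.`, `aff.`, `?`) are rejected
as imprecise; `sp.`/`spp.` names as not species-level; unknown names are
rejected and logged for curation.  The table is validated at load: senior
names must be in the valid-species list, and no chains (the senior of a
senior is itself).

Merging runs before relative abundances are computed, so percentages
reflect merged taxa.  Merged rows sum numeric abundances (set to 1 for
presence/absence samples) and retain the original names and abundances
comma-joined; originals are joined in sorted-by-name order so the merge
is invariant to input permutation.  A sample mixing abundance unit
classes cannot be merged meaningfully and is quarantined.

## Abundance harmonization

Unit classification is per sample: letter codes from the active
vocabulary imply `binned`; numeric values in {0, 1} imply
presence/absence; non-negative integers imply counts; other numerics
imply relative abundance; "number per gram" cannot be distinguished from
counts by values alone and must come as a mapping hint.  Mixed samples
classify by majority, with minority values flagged inconsistent and
valued 0.01 — a deliberate trace value marking "present, recorded
incompatibly".

The default ordinal vocabulary is N, P, R, F, C, A, D → 0…6.  Letter
semantics genuinely vary between datasets ("A" can mean absent or
abundant), so per-dataset override vocabularies are accepted and must be
supplied wherever the default would mislead; no inference is attempted.

`num.ind` is the recorded specimen total where present, otherwise the
within-sample sum; `rel.abun` = 100 × abundance / `num.ind` for count and
per-gram samples (per-gram densities are proportion-normalized within the
sample).  Binned and presence/absence samples keep `rel.abun` absent:
ordinal codes are not proportions, and converting them would fabricate
precision.  Zero-abundance rows are split into a "full" dataset (they
document sampling effort) and excluded from the main one.

## Chronology

Marker events (first/last occurrences, acmes, magnetochron boundaries)
are calibrated through an event table keyed by label, event type, zonal
scheme and region, since the same zone code can denote different datums
under different schemes and some datum ages are basin- and
latitude-dependent.  A region-specific entry is preferred over a `global`
one.  Regions combine basin (Atlantic = 70°W–20°E by default,
configurable) with a tropical/temperate split at |lat| = 23.5°
(inclusive on the tropical side).  The "LO" abbreviation is read in the
context of a study's whole event list: LO with HO means lowest/highest
occurrence; LO mixed with FO means last occurrence.

Events are placed at depth by the midpoint rule: halfway between the last
sample containing the taxon and the first sample from which it is absent
(in the direction the event type implies).  A 0 Ma seafloor tie is added
only when the sediment surface is explicitly declared Holocene, Recent or
Modern.  Tie ages are event-interval midpoints with the interval width
kept as the age range.

## Age-depth models

Ties are split into segments wherever the age gap between
depth-consecutive ties exceeds 10% of the hole's whole tie-age range
(max − min tie age before any split — the literal reading) and at every
declared structural break.  Per segment, up to five estimators:

* **zone** — mean of the bounding tie ages per inter-tie interval, error
  = interval width.  Intervals are half-open `[d_i, d_{i+1})`; without
  this convention every estimator would be trivially exact at tie depths
  and best-fit selection would degenerate.
* **magneto** — the zone mean and (with ≥ 2 magnetic ties) interpolation
  restricted to magnetostratigraphic ties; where a magnetic and a
  biostratigraphic tie coincide in depth, the magnetic one is preferred.
* **interp** — piecewise-linear interpolation between ties (constant
  sedimentation rate per interval); error = the larger of the bracketing
  ties' age ranges (the column is standard, the propagation formula is
  this package's choice).
* **model** — a trend of age on depth: ordinary least squares when fewer
  than 5 ties; otherwise a penalized cubic B-spline (basis size
  min(10, n − 1), uniformly spaced interior knots, second-difference
  penalty) with the smoothing parameter chosen on a log grid by
  generalized cross-validation, GCV(λ) = n·RSS / (n − γ·edf)², with
  γ = 1.1 inflating the effective-degrees-of-freedom cost to guard
  against undersmoothing.  Unadjusted r² and the tie count are recorded.
  The smooth is *not* constrained to be monotone; age reversals are a
  diagnostic signal, not something to cosmetically remove.

Selection minimizes the RMSD between estimator predictions and tie ages
at tie depths; exact ties break in the order interp > model > zone >
magneto (estimators that honour the ties exactly first).  A per-hole
override — standing in for the manual confirmation step a human
stratigrapher would perform — wins outright.  Samples outside every
segment's tie-depth span cannot be dated and are dropped with a logged
reason; samples arriving with a numeric age keep it (`age.calc = orig`).

## Paleocoordinates

The plate model is a standard whitespace-delimited `.rot` file: per
moving plate, age-ordered total rotations (pole latitude, pole longitude,
angle) relative to a fixed plate, forming a circuit to the anchor.
Positive angles are counter-clockwise looking down the pole axis
(right-hand rule).  Between table nodes the total rotation is
interpolated in stage-rotation space — R(f) = R₁·(R₁⁻¹R₂)^f, equivalent
to spherical linear interpolation — never by naively averaging pole
coordinates and angles, which is wrong for large angles.  Rotations
compose through the plate circuit to the anchor.  Records dated 0 Ma keep
their modern coordinates; records whose plate or age the model does not
cover stay unassigned and are removed by the crucial-column filter, with
a log entry.  Plate assignment is an input (a per-hole plate id); this
package does not construct plate polygons.

## Quality control

Duplicates are records identical on species, numeric abundance (to 1e-9,
for float round-trip safety), sample depth, latitude and longitude; one
survives per group, chosen by a configurable source-priority list
(compilation databases before drilling-report extractions before
literature compilations by convention), with rowID as the deterministic
tie-break.

Out-of-range flagging compares each record's assigned age with its
species' known range: more than 2 Ma outside in the Neogene or 5 Ma in
the Paleogene sets `trim = exc`.  The era is keyed to the record's
assigned age with the boundary at 23 Ma (ages < 23 Ma use the 2 Ma rule);
keying to the species' range midpoint instead is a defensible alternative
the implementation exposes via its threshold parameters.  Flagged records
are never deleted — the cut-off is a user decision.

## Validation metrics

Richness is the distinct-species count per half-open 1 Ma bin over
0–66 Ma on the trimmed record set.  Completeness is the fraction of
expected bins occupied, where expected bins are all bins overlapping the
species' closed range [extinction, speciation] — partial bins at the
range ends count as expected, except the degenerate case where the older
endpoint lies exactly on a bin edge (a single-point overlap is not an
expected bin).  This makes completeness monotone under bin refinement:
halving the bin width can never increase it.  The coverage grid counts
records per absolute-paleolatitude band × time bin, folding hemispheres.

## Synthetic cores: what they emulate, and what they do not

The generator produces, per hole: a piecewise-linear age-depth truth
(sedimentation rates per depth piece, optional hiatus with a stated
missing time), regular sample depths, marker events every 0.5 Ma whose
observed tie depths follow the midpoint rule (so observation error is
exactly the half-sample-spacing discretization, with optional Gaussian
depth noise off by default — this keeps estimator error sources
separable), species occurrences wherever the sample's true age falls in
the species' range (detection probability 1 by default), abundances in
the requested encoding, contaminant records placed more than the trim
threshold + 0.5 Ma outside range at the stated per-record rate, and an
exact ledger of records mirrored into a duplicate source.

Default study conditions: 200 m holes at 20 m/Ma (a 10 Ma record, typical
of a continuously cored pelagic section), 1 m sampling, ties every
0.5 Ma, a deterministic 8-species pool spanning the cored window plus two
old "donor" taxa that only ever appear as reworked contaminants, 10%
duplicate overlap and 2% contamination in corpus runs (~5,000 records
over 6 holes).  These sizes keep the full suite and the acceptance script
to well under a minute each while leaving every recovery quantity
measurable.

Passing these tests shows the pipeline's logic is correct under its own
assumptions: exact interpolation through ties, threshold arithmetic,
exact dedup, near-complete contaminant flagging.  It does not show
robustness to what real cores add: non-linear and near-zero sedimentation
rates, datum diachroneity across latitudes, tie ages that are themselves
wrong, partial core recovery remapping depths, or taphonomic loss
patterns.  The completeness and richness values measured on synthetic
corpora are properties of the generator's conditions, not predictions for
any real database.

## Numerical choices and degenerate inputs

Tie lists with duplicate depths collapse to one tie per depth (magnetic
preferred).  Segments with one tie support only the zone estimator; all
ties at one depth make the trend fit unavailable.  GCV λ is searched over
{0} ∪ logspace(−8, 10) with 73 points; candidates whose γ-inflated edf
reach n are discarded.  Zero-angle rotations are represented with the
north-pole axis.  Longitudes normalize to (−180, 180]; the antimeridian
maps to +180.
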