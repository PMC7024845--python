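# Methods

## Model

Classical secretion is treated as a binary, sequence-level decision. A
protein is a candidate for the classical ER→Golgi pathway iff its database
entry carries a signal-peptide feature (+SP); it is withheld from secretion
iff it additionally ends in a C-terminal ER-retrieval tetrapeptide (+XXEL),
which marks it as an ER-resident protein continuously retrieved from the
early Golgi by KDEL receptors. The predicted classical secretome of a
dataset is therefore the set difference

    predicted = {+SP} \ {+SP ∩ +XXEL},      counts: n_predicted = x2 − x3

with x1 = records analysed, x2 = +SP, x3 = +SP ∩ +XXEL. Membership is
binary; no secretion-likelihood score is produced. Two simplifying
assumptions are inherited from the underlying annotation source: +SP status
is whatever the database records as a signal-peptide feature (regardless of
evidence type), and the motif is evaluated on the full sequence including
the signal peptide — anchoring at the C-terminus makes the N-terminal
region irrelevant, so no mature-chain trimming is performed. Known
limitation: the +SP/−XXEL criterion retains membrane proteins and proteins
of secretory-pathway organelles (e.g. lysosomes); the subcellular-location
include/exclude filter exists to narrow these out, but defaults to off, and
a transmembrane-based exclusion is deliberately not applied.

## Motif matching

`match_xxel` examines exactly the final four residues. The default pattern
is positions 1–2 in the 22-letter class `ARNDCQEGHILKMFPSTWYVBZ` (20
standard residues + Asx/Glx ambiguity codes; U and X excluded) and
positions 3–4 fixed to `EL`. Sequences are upper-cased before matching, so
lower-case database dumps cannot silently fail; any non-letter character is
a validation error naming the offending character and position. Sequences
shorter than four residues never match, and a terminal U or X at the last
two positions simply never matches — documented behaviour, not an error.
The pattern is configurable, either as a character-class string
(`[K]{2}EL`) or as an explicit tetrapeptide allow-list, so the
experimentally verified KDEL-variant catalogue can be substituted for the
relaxed class. Narrowing the pattern can only shrink x3 (tested as a
monotonicity property).

## Consensus derivation

`derive_consensus` profiles the final k residues (default k = 4) of a set
of ER-resident sequences: per-position residue counts, exact-tetrapeptide
counts (ordered by count descending, then lexicographically — deterministic
reports), and a consensus string that names a residue only where its
frequency reaches the dominance threshold, else `X`. The default dominance
of 1.0 (unanimity) reproduces the observed outcome on ER-resident sets —
`XXEL`, unanimous only at the EL tail; the threshold is exposed (restricted
to (0.5, 1.0], which guarantees at most one qualifying residue per
position) for sensitivity analysis. For an anchored C-terminal motif this
frequency profiling yields the same consensus a multiple-sequence alignment
would, without any alignment step; no structure-aware alignment is
attempted. ER residents are selected from annotated records by
case-insensitive substring match on location terms (e.g. "endoplasmic
reticulum" matches "endoplasmic reticulum lumen"); evidence codes are not
consulted because the annotation source does not expose a reliable
"experimentally proven" flag per term.

## Annotation

Entries are parsed from UniProt-format XML: sequence with whitespace
stripped, first signal-peptide feature in document order (begin/end
1-based inclusive; an unknown boundary keeps +SP true with
`boundary_known = False`), all subcellular-location terms lower-cased and
de-duplicated in order. An entry lacking a sequence element is treated as
obsolete. The resolver contract is offline-first: a directory of
`<accession>.xml` files (with `<accession>.deleted` markers) or an
in-memory mapping; obsolete, deleted and not-found accessions are excluded
from analysis and enumerated in a report that always satisfies
n_requested = n_annotated + n_excluded. Transient resolver failures are
retried 3 times before a hard error that lists every unresolved accession.
No secondary-accession or ID-history resolution is attempted: obsolete
means excluded. Isoform suffixes are preserved verbatim at the I/O layer;
duplicate accessions are collapsed (first occurrence wins, logged) before
summarising, because summaries count proteins while published lists contain
isoform rows — the collapse can be disabled for strict replication.

## Reporting conventions

Percentages are computed on raw floats and rounded half-up to one decimal
for report strings, with a trailing `.0` dropped (`13.6`, `1`, `30`) to
match the mixed-precision style of published summary tables; raw values
remain available on `DatasetSummary`. Overlap similarity is
reference-relative: 100·|A∩B|/|A|, asymmetric by design — the natural
question for a small granule secretome against a whole-islet secretome is
containment, not Jaccard similarity. Venn region counts are exclusive and
partition the union (verified against inclusion–exclusion in tests).
Cross-species comparisons must use upper-cased gene symbols as keys, since
accessions never match across species; symbol drift and many-to-one
orthology are known, unresolved failure modes of that choice, and no
orthology database is integrated. Mixing key strategies in one comparison
is a configuration error.

## Synthetic data

The generator plants exact quotas, not Bernoulli draws: n_sp =
round(n·frac_sp) records receive a signal-peptide feature (begin 1, end
uniform on 15–30), n_sp_xxel = round(n_sp·frac_xxel_given_sp) of those get
a C-terminus drawn from the KDEL-variant pool ({K,H,S,R,P,E,F,G,D} ×
{D,T,N,E,V,G,A,I,R} × EL), and every other record's final four residues are
rejection-sampled against the default pattern so accidental matches are
impossible. Quota planting lets end-to-end tests assert exact equality of
recovered counts. Location terms are assigned consistently (+XXEL → ER
lumen, other +SP → secreted, rest → cytosolic compartments) and matching
UniProt-style XML is emitted so the parser round-trips records exactly.
Defaults emulate a large human-islet proteome: 13.6% +SP, of which 7.3%
+XXEL; sequence lengths default to 100–600 aa (realistic protein lengths).
What is *not* simulated: mass-spectrometry noise, missing values, protein
abundance, shared peptides, or annotation errors — the tool consumes
identification lists, so passing tests demonstrate correctness of the
filtering arithmetic and plumbing, not robustness to upstream
identification artefacts. All randomness flows from a single integer seed;
identical seeds give byte-identical outputs.

## Problem sizes

The test suite and the acceptance script choose sequence-length ranges of
30–150 aa and dataset sizes up to the largest published row (6745 records)
so a full run completes in seconds; the planted counts, not the sequence
lengths, determine every reported quantity, since the motif window is the
final four residues regardless of length.

## Numerical and degenerate-input choices

Half-up rounding everywhere a count or percentage is reported (via
`decimal`, avoiding binary-float ties). Empty input lists yield empty
outputs with a logged warning rather than an error; an empty consensus
input set is an error (there is no meaningful profile of nothing). An empty
include-term list keeps all records; exclusion always takes precedence over
inclusion. Ties in tetrapeptide ordering break lexicographically.
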