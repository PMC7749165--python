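# Methods

## Crosslink distance classification

The analysis unit is the unique unordered residue pair. Input tables are
expected to come from an upstream identification/FDR workflow (e.g.
xiSEARCH/xiFDR exports); the package only thresholds the residue-pair FDR
column (default 0.05) and collapses duplicate pairs, keeping the lowest
FDR. Links without an FDR value pass the filter with a warning rather
than being dropped, since some export formats omit the column for
high-confidence subsets.

Distances are Cα–Cα only. A link is *within* if d ≤ L and *over-length*
otherwise, with the boundary d = L classed as within ("within L" is read
inclusively). The default limit L = 25 Å is the theoretical Cα–Cα span of
sulfo-SDA, whose NHS-ester end reacts with lysine, serine, threonine,
tyrosine and protein N-termini while the photo-activated diazirine end
inserts into any residue. Sites whose residue or Cα is not modeled are
reported as *unmapped* with a reason — never imputed from another atom —
so every mapping run conserves n_within + n_over + n_unmapped = n_links.

When a subunit role maps to several chains (homodimers, dimeric
assemblies), every role-consistent chain combination is evaluated and the
minimum distance is assigned. This is the conservative convention of the
field: a crosslink is explained if *any* copy explains it. The chosen
chain pair is recorded per link.

## Random-pair null

The null distribution enumerates all unordered residue pairs with a
modeled Cα (intra- and inter-chain) by default; typical single complexes
are small enough that exhaustive enumeration is cheap. A seeded sampled
mode draws uniformly without replacement from the same pair universe for
very large assemblies. An optional reactivity restriction limits the
universe to pairs where at least one side is K/S/T/Y or an N-terminus,
matching the NHS-ester chemistry; it is off by default because the plain
"random residue pairs" null is the more common reference and the two
differ little in practice on mixed-sequence proteins. Both modes are
available so either convention can be reported explicitly.

## Region-pair counting

Regions are author-numbered intervals on one subunit role (e.g. β
146–248; β′ 794–1141). The count matrix is symmetric over unique links;
links outside every region fall into an "other" bin so totals remain
conserved. Overlapping regions on one role are rejected rather than
double-counted.

## Superposition and measurements

Rigid-body fitting uses the closed-form Kabsch solution (SVD of the
cross-covariance of the centred point sets, determinant-corrected to
exclude reflections). Degenerate inputs — fewer than three pairs, or
rank-deficient (collinear) clouds — are errors, not warnings, because the
rotation is underdetermined there. Residue equivalences come from three
sources: shared role + author number, a superposition-derived nearest-Cα
matching (greedy nearest-first, one-to-one, 3.5 Å default cutoff, ties
broken toward lower residue number), or a user-supplied 4-column file.
The structural matching is anchored on a user-chosen subunit — for
RNAP-family comparisons the β subunit is the customary anchor — and is
intentionally greedy rather than globally optimal: it is deterministic,
fast, and adequate for conserved cores, while unmatched peripheral
residues are simply dropped from the equivalence.

Named distances default to Cα. Where the chain assignment of a site is
ambiguous, all combinations are computed and the minimum is the headline
value, with the full list available. Channel-width deltas are signed:
positive means wider in the first model.

## SASA and buried interfaces

Shrake–Rupley quadrature with a deterministic golden-spiral point set
(default 960 points per atom, probe 1.4 Å) on spheres of radius
r_vdW + r_probe. The van der Waals table is Bondi-type (C 1.70, N 1.55,
O 1.52, S 1.80 Å, ...), with metals (Mg, Zn) included and a 1.70 Å
default for unknown elements; hydrogens and waters are excluded. The
kd-tree neighbour search is an exact pruning of the all-pairs occlusion
loop — the test suite checks bitwise equality against an independent
brute-force implementation, and the single-atom case against the analytic
sphere area. The choice of radii table, probe and point count is a
documented default of this package, configurable in every entry point; no
claim is made that any particular published buried-area figure was
produced with the same convention, which is why cross-study comparisons
should use generous (~10%) tolerances.

Buried area is the **two-sided** ΔSASA, SASA(A) + SASA(B) − SASA(A∪B),
with both groups kept in their in-complex coordinates. The two-sided
convention is used because per-partner values then sum to the combined
interface total (as in published RNAP–HelD interface decompositions where
≈8000 + 1800 + 1700 ≈ 11,500 Å²). The decomposition reports any
discrepancy between the sum of pairwise buried areas and the
all-partners-combined value; a non-zero discrepancy indicates three-body
shielding.

## Synthetic data

Toy complexes are CA traces: ideal helices (1.5 Å rise, 100°/residue
twist, 2.3 Å radius) or straight strands (3.8 Å step), laid side by side
12 Å apart, each rotated about its own axis by a seeded random phase.
Residue names cycle through a fixed 10-name list of which four (K/S/T/Y)
are NHS-reactive, so reactivity-restricted operations are exercised. An
optional hinge rotates the distal part of one chain about an axis through
the split-point Cα, swinging it away from the neighbouring chains; a 0°
hinge is bit-identical to no hinge. This emulates clamp-like domain
opening: crosslinks drawn from the closed conformation become over-length
when mapped onto opened copies, and the over-length fraction grows with
the opening angle.

The simulator draws round((1−f)·n) links from residue pairs within the
limit and round(f·n) from pairs beyond it, uniformly without replacement,
with FDR values uniform in (0, 0.05] and optional reactivity restriction.
The planted fraction f is the ground truth that the full pipeline must
recover; defaults used throughout the tests and the acceptance script are
n = 1000 links on a 160-residue three-chain complex, f ∈ {0, 0.1, 0.3,
0.5}, and hinge angles 0–60°. These sizes keep every check exhaustive or
near-exhaustive while exercising the same code paths as full-size
structures.

What the toys do **not** emulate: side-chain geometry (the simulation and
the analysis both operate on Cα distances, so agreement between them
validates the statistic, not crosslinker chemistry), spectrum-level
identification noise, decoy-based FDR behaviour, or realistic protein
packing. Passing the synthetic suites therefore shows the pipeline
measures what it claims on data with known truth; accuracy on real
structures is checked separately by the deposited-structure measurement
suite, which requires the public coordinate archive.

## Numerical choices

- Altlocs resolve to the highest occupancy, ties to first occurrence;
  first coordinate model only.
- Author residue numbering throughout (auth_seq_id in mmCIF), because
  that is how residues are cited in the structural literature.
- Classification boundary d = L is *within*; fractions are computed over
  unique pairs after deduplication.
- All sampling (null draws, simulated links, toy phases) uses explicit
  seeds through `numpy.random.default_rng`; identical configs reproduce
  report tables byte-for-byte.
- PDB round-trips preserve coordinates to the format's 1e-3 Å precision.

## Limitations

- The nearest-Cα equivalence is greedy, not an optimal assignment; for
  highly diverged structures a curated mapping file is the better input.
- Buried-area values depend on the radii/probe/point-count convention;
  only same-convention comparisons are meaningful at the ~1% level.
- Links to proteins absent from the subunit map are retained in tables
  but excluded from structure mapping (reported per link), so fractions
  refer to mappable links only.
- The intrinsically disordered δ C-terminal region is typically only
  partially modeled in deposited RNAP–δ–HelD coordinates, so interface
  areas involving δ systematically under-report the full subunit's
  contribution.
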