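# pepscreen

Two-stage in-silico screen for peptide variants that bind a rigid receptor
groove more tightly than the template peptide, on a fixed poly-Gly scaffold.

Given a peptide–receptor complex (PDB), the pipeline:

1. replaces every peptide side chain with Gly while preserving the main
   chain bit-identically (`build_gly_scaffold`);
2. **stage 1** — substitutes each non-frozen position with every alphabet
   residue (coarse χ-grid rotamers, clash-filtered), scores each single
   substitution with a five-term empirical binding free-energy function,
   and keeps residues that beat the all-Gly baseline;
3. applies a declarative candidate-selection rule (top-k above the original,
   forced inclusions, frozen positions) to build per-position candidate
   sets;
4. **stage 2** — exhaustively builds and scores every cross-product sequence
   and ranks the full-length peptides by score.

The scoring function is

```
dG_total = dG0 + dG_polar + dG_apolar + dG_solv + dG_flexi    [kcal/mol]
score    = -100/(ln10 · R · T) · dG_total  =  -100 · log10(Ki)
```

with hydrogen-bond/ionic terms under piecewise-linear distance and angle
penalties, a lipophilic contact area plus aromatic-stacking term (numeric
rolling-probe surface areas, probe 1.4 Å), a desolvation penalty for buried
uncompensated polar atoms, and a rotatable-bond fixation penalty.  At 298 K
the score coefficient is 73.34 (≈ the conventional 73.33).

A synthetic-complex generator (`pepscreen.synthetic`) builds toy pockets
with *planted*, analytically known interaction sites around an ideal
extended 14-mer backbone, so the whole pipeline is testable offline with
provable ground truth; it also packages the published candidate-table and
sequence fixtures used by the tests.

## CLI

```
# full screen on a PDB complex
screen run --pdb complex.pdb --peptide-chain C \
    --score-config score.yml --screen-config screen.yml --out results/
# -> candidates.tsv (stage-1 table), ranked.tsv (rank, R1..R14, score),
#    top.fasta, run.log

# exact combinatorial library size
screen size --counts 5,6,8,5,4,4,3,8,1,1,8,2,5,2

# synthetic toy complex + ground-truth sidecar
screen synth --spec spec.yml --seed 7 --out toy.pdb
```

Default configuration files (all keys overridable) live in
`src/pepscreen/data/score_defaults.yaml` and `screen_defaults.yaml`.

## Tests

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (enumeration
count/content on the packaged fixture, library-size combinatorics, the
score-conversion coefficient, and the property suites: additivity,
rigid-body invariance, oracle-equivalent ranking, planted-optimum recovery,
backbone conservation, monotonicity).

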