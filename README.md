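# casbind

Energy-based modelling of Cas9–gRNA–DNA binding with sliding-PAM-aware
guide specificity scoring.

The package computes the composite binding free energy change

    dG_B = delta_PAM * (dG_H - dG_U - dG_O)

from positionally weighted RNA–DNA nearest-neighbour stacking (`dG_H`), a
DNA-opening penalty over the engaged target stretch (`dG_O`) and the
spacer's self-folding MFE (`dG_U`). On top of this it provides:

- **Sliding-PAM detection and scoring** — guanines flanking the 4-nt PAM
  context `N-1 G G N+1` open overlapping PAMs one step up/downstream; the
  bulged gRNA–DNA hybrids they enable (RNA bulge at the PAM-proximal spacer
  base upstream, DNA bulge between hybrid and PAM downstream) are detected
  and scored, for canonical and non-canonical binding motifs and for
  NG-compatible Cas9 variant profiles.
- **Off-target enumeration** — a desk-scale both-strand FASTA scanner with
  IUPAC PAM patterns and a mismatch budget, plus competing-PAM resolution
  (lowest `dG_B` wins).
- **Specificity scores** — the partition-function competition score
  (−log10 of the Boltzmann-weighted off-target share of total binding) and
  its extension with least-squares-fitted local sliding contributions,
  including tertile binning of scores.
- **Dataset statistics** — indel frequencies, read-threshold selection,
  replicate averaging, specificity/efficiency filters, scaffold-structure
  distances, similarity-aware train/test splitting, top/bottom-20% splits,
  80%-coverage sweet-spot intervals, logo frequency matrices, GUIDE-seq
  site filtering, sliding-condition variance decomposition and PAM-pattern
  group tests.
- **Synthetic fixtures and brute-force oracles** — seeded toy genomes with
  planted sites, simulated efficiency datasets with known coefficients, and
  exhaustive enumeration oracles that double-check the production
  algorithms in the test suite.

## Parameter tables

`src/casbind/data/nn_params_v1.json` ships Watson–Crick nearest-neighbour
stacking free energies (RNA–DNA hybrid: Sugimoto 1995; DNA–DNA: SantaLucia
1998 unified; RNA–RNA: Xia 1998) plus single-nucleotide bulge steps for the
two homoduplexes (literature loop penalties split across the two flanking
steps). RNA–DNA bulge steps are completed at load time by averaging the two
homoduplex counterparts. The default positional weights are **uniform 1.0**
(version-tagged `uniform-1.0`): the fitted 19-weight profile belongs to the
CRISPRoff distribution and must be supplied by the user to reproduce
published energy values. Any parameter file in the same JSON schema can be
passed to the CLI and loaders; unversioned files are refused.

## CLI

```sh
casbind energy --spacer GACGCAUAAAGAUGAGACGC --target ACGT<20nt>TGGACC
casbind energy --batch guides.tsv --out energies.tsv
casbind scan --spacer <spacer> --genome genome.fa --max-mismatches 6 --bed hits.bed
casbind spec --spacer <spacer> --target <30mer> --genome genome.fa --model model.json
casbind fit --input training.tsv --out model.json
casbind analyze --input efficiencies.tsv --outdir analysis/
casbind simulate --seed 1 --outdir fixtures/
```

`energy` emits per-target `dG_H/dG_O/dG_U/dG_B` with a compact M/X/I/D
alignment string; `spec` composes scan → energies → specificity (and the
extended score when a fitted model is given); `fit`/`analyze` wrap the
model fitting and dataset statistics. Exit code 2 flags validation errors.
Output TSVs carry `#` headers with tool and parameter-set versions, a
config digest and the seed.

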