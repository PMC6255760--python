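# cardfil

Screw-symmetry filament modelling and analysis for CARD-like death-fold
filaments. The package implements, end to end and fully testable on synthetic
data:

- **helical geometry** — the screw operator, filament construction from
  (rise, twist), pitch / protrusion-spacing / subunits-per-turn arithmetic,
  and recovery of (rise, twist) from a filament by least-squares
  superposition of consecutive subunits;
- **structure I/O** — PDB/mmCIF reading (via biotite), fixed-width PDB
  writing, configuration-driven helix segmentation and surface-patch labels;
- **synthetic data** — a five-helix pseudo-atom monomer (~40x25x25 A) with
  engineered interface patches and formal charges, plus a projection-image
  renderer (Gaussian splat + white noise, MRC/PNG output) with known ground
  truth;
- **layer-line analysis** — axial autocorrelation of the filament-edge
  profile for the visual protrusion spacing, meridional power-spectrum
  profiles, helical-rise estimation from the furthest layer line, and the
  twist-sign (handedness) ambiguity of a single 2D projection;
- **interface analysis** — inter-subunit heavy-atom contact mapping and
  majority-vote classification into death-fold Type I/II/III interfaces
  from the six canonical half-patches (Ia/Ib, IIa/IIb, IIIa/IIIb), plus the
  top/bottom/lateral surface partition;
- **mutation design** — a minimal charge-product model predicting
  loss / rescue / enhanced / ambiguous outcomes of charge-reversal
  mutations, and the top/bottom surface-silencing designs.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (pitch arithmetic,
segment count, symmetry round-trip, layer-line rise recovery at SNR >= 2,
interface classification on ground truth and decoys, and the mutation
predictor panel), one test per criterion.

## CLI

```sh
cardfil pitch --rise 4.96 --twist 101.36            # pitch numbers side by side
cardfil build --seed 1 --n 12 --out filament.pdb    # 12-chain filament PDB
cardfil simulate --seed 1 --out-prefix scratch/run  # monomer/filament/micrograph
cardfil layerlines --image scratch/run.mrc --out profile.tsv
cardfil interfaces --seed 1 --n 12 --out classes.tsv
cardfil mutscan --mutations "E445R,R458E"
```

Every stochastic stage requires an explicit `--seed`; TSV outputs are
byte-reproducible for fixed seeds. A plain `key=value` config file can be
passed with `--config`; flags override it.

## Conventions

- Filament axis is +z in a right-handed frame; positive twist is
  counterclockwise viewed from +z; negative twist means a left-handed
  filament. Default parameters: rise 4.936 A, twist -101.4 deg, C1.
- Angles are degrees at every public interface; coordinates are Angstrom.
- Residue numbering follows the full-length protein (CARD = 432-540); no
  local renumbering.
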