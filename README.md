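# ciliacoat

Quantitative analysis of the ciliary glycocalyx — the scale-like
glycoprotein coat on the outside of the ciliary membrane of
*Chlamydomonas reinhardtii* — for three kinds of data:

1. **Cryo-electron tomograms.** Fit the ciliary membrane per slice with a
   closed spline, offset it by a distance field into a *shell mask*
   containing the glycocalyx band, then locate individual coat particles by
   rotation-searched, locally normalized cross-correlation and a greedy
   overlap-exclusion filter that fills accepted particles into a simulated
   occupancy volume.
2. **Chain models of the coat protein.** The coat glycoprotein is a
   mucin-like chain of ~110-residue Ig-like structural repeats that share
   their fold but almost no sequence. The package segments such chains into
   repeats by Kabsch superposition, computes all-vs-all RMSD matrices and a
   structure-guided multiple alignment, finds conserved columns (notably a
   fully conserved cysteine pair forming one disulfide per repeat), and
   reports pairwise sequence identities (Needleman–Wunsch/BLOSUM62).
3. **Time-lapse microscopy.** Gliding motility is quantified from
   kymographs (velocity = track slope × pixel size / frame interval, with
   the "velocity > 0" inclusion rule and Mann–Whitney U comparisons), and
   ciliary adhesion from microfluidic detachment movies (per-frame Otsu
   binarization, occupancy normalized to frame 0, stepwise flow schedule,
   Student t tests at fixed timepoints).

Since real tomograms and movies are not repository-scale inputs, every
stage has a synthetic generator with known ground truth (`ciliacoat.synthetic`),
and the test suite validates the pipeline against that truth — e.g. coat
mapping must recover ≥ 90% of planted particles within 2 voxels at
realistic noise with a ±60° missing wedge.

## Worked example

Simulate a coated-tube tomogram phantom and map its coat:

```
$ ciliacoat simulate --kind tomogram --seed 1 -o phantom.mrc
phantom.mrc
$ ciliacoat map-coat --volume phantom.mrc --membrane phantom.membrane.csv \
      --grid-step 20 --threshold 0.4 -o particles.tsv
49 particles -> particles.tsv
```

`particles.tsv` holds sub-voxel positions, ZYZ orientations and correlation
scores; `particles.json` summarizes the mapped coat:

```json
{
  "count": 49,
  "surface_density_per_um2": 1560.7,
  "mean_shell_radius_angstrom": 446.1,
  "mean_nn_distance_angstrom": 163.3,
  "median_normal_angle_deg": 24.4,
  "n_orientations": 1908
}
```

i.e. 49 of the 50 planted particles found on the coat band at ~450 Å from
the tube axis, ~160 Å apart, with matched orientations a median 24° from
the outward membrane normal (the phantom plants them normal-aligned; the
residual reflects the 20° rotation-grid discretization plus noise-driven
orientation error at σ = 0.3·peak). The same library calls are available
in Python:

```python
from ciliacoat.synthetic import TomoPhantomSpec, simulate_tomogram
from ciliacoat.matching import make_rotation_grid, match_template, extract_peaks, overlap_filter

spec = TomoPhantomSpec(seed=1)
vol, truth = simulate_tomogram(spec)
```

The other stages follow the same pattern:

```
ciliacoat simulate --kind chain --seed 3 -o chain.pdb
ciliacoat analyze-repeats --model chain.pdb -o rep       # 5 repeats, Cys at columns 60/91
ciliacoat simulate --kind gliding --seed 2 -o glide.tif
ciliacoat analyze-motility --movie glide.tif -o events.csv   # 0.97 µm/s recovered
ciliacoat simulate --kind detachment --seed 5 -o det.tif
ciliacoat analyze-detachment --group-a det.tif,... --frame-interval 1.0 -o curves.csv
```

`rep.summary.json` for the chain above reports 5 segments of mean length
100, mean pairwise repeat identity ≈ 22%, the conserved cysteine columns
`[60, 91]` and one disulfide per repeat — the synthetic analogue of a
repeat family with high structural but low sequence conservation.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and the limits of what the synthetic validation shows.

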