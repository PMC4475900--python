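# jpca — rotational neural population dynamics

Tools for asking whether the population activity of motor cortex
during movement behaves like a dynamical system that *rotates* from a
condition-dependent pre-movement state, as observed in multi-electrode
recordings during center-out movement tasks.  The package is written
for systems neuroscientists working with trial-structured spike data
(binned counts per electrode, a condition label per trial) and
provides the full analysis chain: trial averaging, Gaussian smoothing,
soft normalisation, mean-centering, PCA, skew-symmetric dynamics
fitting (jPCA), rotational-structure statistics, surrogate shuffle
controls, and a synthetic-data generator with known ground-truth
dynamics for validation.

## The method

After preprocessing, the reduced population state `X_red` (top *d*
PCs, default 6, organised as condition blocks) and its per-bin changes
`Ẋ_red` are related by two linear models,

```
Ẋ_red = M X_red          (M unconstrained, least squares)
Ẋ_red = M_skew X_red     (M_skew = −M_skewᵀ, skew-symmetric)
```

A skew-symmetric transition matrix has purely imaginary eigenvalues
and can only generate rotations.  The fraction of state-change
variance it explains,
`R²_skew = 1 − ‖Ẋ − M_skew X‖²_F / ‖Ẋ‖²_F`,
quantifies rotational structure; eigenvector pairs of `M_skew` with
the largest |eigenvalues| span the jPCA planes, each oriented so the
pre-movement states spread along jPC₁ and rotation is
counterclockwise.  Shuffle controls (condition-wise inversion of
movement-epoch patterns, and cross-condition reassignment) test that
rotations are a property of the data's cross-channel structure rather
than an artifact of the method.

## Worked example

```python
import jpca

# synthetic recording: 8 conditions, 40 electrodes, 100 trials each,
# latent rotation planes at 2.5 Hz and 1 Hz behind Poisson spiking
trials = jpca.make_rotational_trialset(seed=3)

res = jpca.JPCA.from_trialset(trials).fit()
print(res.summary())
```

```
jPCA rotational dynamics fit
================================================================
reduced dims (d):        6
conditions x time bins:  8 x 25
bin width:               10 ms
R2 (unconstrained M):    0.9373
R2 (skew-symmetric M):   0.8974
----------------------------------------------------------------
plane  freq (Hz)  var. reduced  var. full
    1      2.197         0.603      0.593
    2      1.020         0.378      0.372
    3      0.432         0.019      0.019
================================================================
```

Pure rotations explain 90% of the state-change variance — almost as
much as the unconstrained linear model (94%) — and the top jPCA plane
rotates at ≈2.2 Hz while capturing 59% of the variance of the
high-dimensional (soft-normalised, centered) data.  The plane
frequencies approach the planted 2.5/1 Hz; smoothing and Poisson noise
bias the top-plane estimate slightly downward.

The shuffle control inverts each channel's movement-epoch pattern for
a random half of the conditions and re-runs the whole analysis:

```python
sh = jpca.run_shuffle_suite(trials, "invert_half", n_shuffles=300, seed=3)
print(f"invert_half: original r2_skew={sh.original_r2:.3f}, "
      f"shuffled {sh.mean:.3f} +/- {sh.sd:.3f}")
```

```
invert_half: original r2_skew=0.897, shuffled 0.355 +/- 0.075
```

Destroying the cross-channel phase structure collapses the rotational
variance fraction, as it should when the rotations are real.

Trajectory and histogram figures mirror the standard presentation:

```python
from jpca.plotting import plot_plane_trajectories, plot_angle_histogram
plot_plane_trajectories(res.project(0))        # top-plane trajectories
plot_angle_histogram(res.angle_distribution()) # state/derivative angles
```

## Command line

The same pipeline is available as a CLI over HDF5 containers and YAML
configs:

```
jpca simulate -c config.yaml -o data.h5
jpca analyze  -i data.h5 -d results/ --figures
jpca shuffle  -i data.h5 -d results/ -k invert_half -k reassign
jpca report   -d results/
```

Every output bundle carries provenance (config echo and hash, seed,
package version), and all results are bit-reproducible from
(data, config, seed).

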