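# lcrtrack

Motion stabilization and automated detection of **local Ca²⁺ releases
(LCRs)** in 2D fluorescence movies of spontaneously beating cardiac
pacemaker (sinoatrial node) cells.

Pacemaker cells beat on their own: every cycle the cell contracts and a
whole-cell, action-potential-induced Ca²⁺ transient floods the
cytoplasm. Between beats, during diastolic depolarization, small
stochastic Ca²⁺ releases appear, propagate, split, merge, and either
fade away or fuse into the next transient. Quantifying them requires
(1) removing the motion artifact of the contraction and (2) separating
a weak local signal from the global transient and from camera noise.
`lcrtrack` implements both stages as a scriptable library with a CLI,
plus a ground-truthed movie simulator for validation.

## The two algorithms

**Stabilization.** The cell, lying roughly along the x axis, is reduced
per frame to a spine: for every column,

    ζ(x,t) = Σ_y y·a(x,y,t)^1.5 / Σ_y a(x,y,t)^1.5,
    a = i − b  where  i > b + 3σ,  else 0,

with `b`, `σ` the background mean and SD. The spine's local curvature
`k(t,x) = ζ_xx / (1 + ζ_x²)^{3/2}` (Savitzky–Golay derivatives) is
conserved under contraction, so curvature bands act as trackable
landmarks. One contraction is designated as a template and matched
against the rest of the recording by least difference; guide lines bent
inside the template window are replayed in every matched window,
yielding tracked spine points. Those points carry a strip of isosceles
triangles (apexes ±h above/below the spine), and each frame is
backward-warped into the reference geometry triangle-by-triangle with
the affine map `M_d · M_r⁻¹` of homogeneous vertex matrices.

**Detection.** On the stabilized stack: the *Max Filter* segments the
cell (per-pixel temporal maxima, cut at their mean); intensities are
rescaled to 0–255 (`F_norm = 255 (F − F_min)/(F_max − F_min)`); the
*Decay Filter* subtracts the whole-cell average trace `F_a(t)` and
clips negatives, removing the global transient; a composite
*Differential Filter* spatially averages over a `(2d+1)²` window
(default `d = 3`, i.e. 7×7) and takes frame-to-frame differences `D`.
Pixels with `D` above `SD Detection` noise SDs become LCR candidates
(plus a 7-of-8-neighbor fill); 4-connected candidate clusters found new
events only if they are simultaneously large enough (*Size Threshold*)
and bright enough (*Intensity Threshold*). Events keep their identity
through growth and splitting, the largest participant survives a
collision, and an event dies by stochastic attrition (mean signal below
`SD Termination` SDs), by collision, or by merging into the rising
transient (the *% Transient Cutoff* suspension). Each event is reported
with 17 parameters (bounding box, start/max/path area, cycle-relative
birth times, duration, half-max amplitude, death mode) plus a per-frame
size trace.

## Worked example

```sh
lcrtrack simulate --out demo --seed 5 --contraction-amplitude 0.0
lcrtrack detect demo/movie.tif --out demo/det
lcrtrack score demo/truth.csv demo/det/events.csv
lcrtrack fpcheck demo/movie.tif --control-region 8,2,100,10
```

which prints

```
wrote demo/movie.tif (100 frames), 20 seeded events
20 LCR(s) detected; cell area 4406 px; sigma_cell=0.789
recall=1.000 precision=1.000 birth_frame_MAE=0.25 (matched 20/20 truth, 20 detected)
control: 0 event(s) / 1000 px; cell: 20 event(s) / 4406 px; fp_rate = 0.00%
```

The simulated movie holds two 50-frame pacemaker cycles (10 ms/frame)
with 10 events per cycle at five times the camera noise SD; the
detector recovers all 20 with birth frames accurate to a quarter of a
frame on average, and an off-cell control region of 1000 px yields no
spurious events. Programmatically the same run is:

```python
from lcrtrack import simulate_movie, run_detector, score_detection, RunConfig

stack, truth = simulate_movie(contraction_amplitude=0.0, seed=5)
result = run_detector(stack, RunConfig())
print(score_detection(truth, result.records))
```

For a contracting movie, `lcrtrack stabilize` consumes the scripted
equivalents of the interactive steps (background rectangle, template
window, guide columns, bend polyline) from the config file and writes
the stabilized TIFF plus the matched contraction windows and per-frame
mesh vertices; see `tests/test_cli.py` for a complete example.

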