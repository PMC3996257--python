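# ermetrics

Quantifying macular contraction in idiopathic epiretinal membrane (ERM)
from paired infrared fundus photographs.

An ERM is a fibrocellular sheet on the inner retinal surface. As it
contracts it drags the macular capillaries inward, wrinkles them, and
thickens the retina; vitrectomy with membrane peeling releases the
traction. `ermetrics` implements a reproducible measurement pipeline for
this displacement — for retina researchers who have registered pre- and
post-operative infrared fundus images (e.g. Spectralis AutoRescan pairs),
per-ETDRS-subfield OCT thickness tables, and visual acuity, and want
objective numbers for how far the vessels moved and whether that movement
tracks thickness and acuity.

## The two metrics

Both are defined on a *modified ETDRS grid*: the standard fovea-centred
1 / 3 / 6 mm rings, with the nine standard subfields simplified to five —
central (1 mm disc) plus superior, inferior, nasal and temporal quadrants
bounded by the ±45° diagonals.

* **VLA** (vessel segment length in area): per quadrant, the mean arc
  length of 3–5 fovea-directed ("radial") vessels clipped between the
  1 mm and 6 mm rings. A contracted, tortuous vessel packs more arc
  length into the annulus, so VLA falls after surgical release
  (ΔVLA = VLA_pre − VLA_post > 0).
* **FBL** (foveola-to-branching-point length): in the superior and
  inferior quadrants, the sum of the straight-line foveola distances of
  the five vessel branching points nearest the foveola, with the *same*
  five points re-measured in the follow-up image via cross-visit
  correspondence. Inward traction shortens these distances, so FBL rises
  after release (ΔFBL = FBL_post − FBL_pre > 0).

Paired pre/post comparisons use the exact Wilcoxon signed-rank test (full
sign-assignment null distribution — at a 16-eye cohort the p-value is
exact, not approximated), and Δ-vs-Δ associations use Spearman rank
correlation (exact by permutation at very small n).

Because clinical image sets of this kind are not publicly deposited, the
package includes a first-class synthetic-fundus module: branching radial
vasculature around a fovea, a parameterised contraction field
(inward radial pull with a Gaussian radial envelope, tangential
wrinkling, nasal attenuation from optic-disc anchoring), infrared-style
renders, and analytic ground truth for every metric — so the whole
pipeline is testable end to end.

## Worked example

Simulate one eye, contract it, render both visits, and measure:

```python
from ermetrics import (ContractionField, ETDRSGrid, apply_contraction,
                       generate_vessel_tree, render_fundus, extract_graph,
                       compute_vla, detect_branch_points)
from ermetrics.grid_metrics import compute_fbl_pair, match_branch_points

tree = generate_vessel_tree(arcades=8, branch_depth=3, seed=7)
erm = ContractionField(amplitude=0.25, wrinkle_amp_um=42.0, nasal_attenuation=0.3)
pre_tree = apply_contraction(tree, erm, seed=7)   # pre-op = contracted state

grid = ETDRSGrid(laterality="OD")
pre = extract_graph(render_fundus(pre_tree, noise_sd=3.0, seed=1))
post = extract_graph(render_fundus(tree, noise_sd=3.0, seed=2))

vla_pre, vla_post = compute_vla(pre, grid), compute_vla(post, grid)
for q in ("superior", "inferior", "nasal", "temporal"):
    a, b = vla_pre[q].mean_um, vla_post[q].mean_um
    print(f"VLA {q:9s} pre {a:7.1f}  post {b:7.1f}  dVLA {a-b:+7.1f} um")

pts_pre, pts_post = detect_branch_points(pre, grid), detect_branch_points(post, grid)
match = match_branch_points(pts_pre, pts_post, max_shift_um=300.0)
for q in ("superior", "inferior"):
    f_pre, f_post = compute_fbl_pair(pts_pre, pts_post, q, match)
    if f_post.missing:
        print(f"FBL {q:9s} pre {f_pre.sum_um:7.1f}  post missing ({f_post.note})")
    else:
        print(f"FBL {q:9s} pre {f_pre.sum_um:7.1f}  post {f_post.sum_um:7.1f}  "
              f"dFBL {f_post.sum_um - f_pre.sum_um:+7.1f} um")
```

prints

```
VLA superior  pre  2694.9  post  2546.9  dVLA  +148.0 um
VLA inferior  pre  2732.0  post  2612.3  dVLA  +119.8 um
VLA nasal     pre  2566.9  post  2556.5  dVLA   +10.4 um
VLA temporal  pre  2797.6  post  2544.4  dVLA  +253.3 um
FBL superior  pre  7216.7  post  7904.0  dFBL  +687.4 um
FBL inferior  pre  6942.5  post missing (pre branch point 'n95' unmatched in post visit)
```

Reading this: every quadrant's VLA fell after release (the wrinkled
pre-operative vessels carried extra arc length), and least in the nasal
quadrant, where the optic disc anchors the retina and the membrane can
pull only weakly — the same area-dependence seen clinically. The
superior FBL grew by ~0.7 mm: the five tracked branching points moved
back away from the fovea. The inferior FBL pair is honestly reported as
missing because one of the five pre-operative points found no mutual
nearest-neighbour partner within 300 μm in the follow-up image — missing
components propagate, they are never silently imputed.

## Command line

```bash
ermetrics simulate --n-eyes 16 --seed 7 --outdir cohort/       # synthetic study
ermetrics extract cohort/eye00_pre.png --out eye00_pre.json    # centerline graph
ermetrics metrics eye00_pre.json --visit pre --out m.json      # VLA + branch points
ermetrics pair eye00_pre.json eye00_post.json --out pair.csv   # paired deltas
ermetrics analyze cohort.csv --out report/                     # Wilcoxon + Spearman tables
ermetrics run --seed 7 --n-eyes 16 --outdir study/             # everything end to end
```

Real images are accepted as grayscale PNG/TIFF with a JSON sidecar giving
`scale_um_per_px`, the marked `foveola_px` and laterality; thickness
tables as CSV (μm per subfield).

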