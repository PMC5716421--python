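# Methods

## Delivery model

A plan is a sequence of control points; between consecutive control points
every axis (gantry angle, 40 leaf pairs per bank, backup jaws) is linear in
cumulative MU — the interpolation rule of the delivery controller.  Plans
are built in the MU domain from per-pair piecewise-linear trajectories;
breakpoints are snapped onto the 0.1 MU entry grid *keeping their
positions*, so trajectory corners (reversal apexes, dwell boundaries, picket
manoeuvres) are exact and only the inter-breakpoint speeds absorb the
quantisation.  This matters: sampling the continuous trajectory at quantised
MU instead would clip every corner by up to `0.05 MU × dx/dMU` and shift
fluence ramps by tens of microns.

For each segment the controller picks the highest dose-rate bin
`DR_max / 2^k` (six bins by default) for which every axis speed
`travel × DR / ΔMU` is within its limit; a speed exactly at the limit is
feasible.  Plans may carry a per-segment *planned* dose rate (the intent a
physicist would type into the test file); the simulator treats it as an
upper bound on the bin, never as permission to exceed a limit.  When even
the lowest bin cannot satisfy an axis — or the planned rate exceeds the
machine maximum, as in the deliberate 1.2× strips — the axis is capped at
its maximum and the segment stretched in time, so the full MU is always
delivered ("the dose is still correctly delivered"); a cap event is logged.
Total delivered MU equals the plan total exactly in every case, including
capped segments.

Most strip tests need no dose-rate hint at all: holding the gantry speed at
the value fixed by the `ΔMU/Δθ ≥ 0.1 MU/°` floor evaluated at `DR_max/32`
(3.125 °/s at the defaults) makes the gantry demand `Δθ/ΔMU` force exactly
the intended bin in every strip, because adjacent bins differ by a factor
2 while the feasibility margin is 1.92.

### Injectable errors

* **Dose-rate switch lag** — after a bin change the previous bin's rate
  holds for `dr_switch_lag` seconds (0.25 s is the literature settling
  value), then the new bin's rate applies; the resulting MU surplus/deficit
  is settled at the very end of delivery (terminal dwell or early beam-off)
  so the total MU stays exact while the junction excursion stays local:
  the profile returns to unity within `v_leaf × lag` past the junction
  (2.5 mm at 1 cm/s and 0.25 s), on top of the `gap`-wide open-window
  mixing zone.  Whether a real controller ramps through intermediate bins
  is not known to us; the lag is a stand-in, and reports should treat its
  magnitudes as qualitative.
* **Reversal over-travel** — at every change of leaf direction the leaf
  leaves the planned path `δ/v` before the programmed apex, runs `δ` past
  it at twice the leg speed, and rejoins `δ/v` after.  The perturbation is
  a time-symmetric local triangle: open-time change `±(δ − |x − apex|)/v`,
  peak `δ/v`, area `δ²/v`, positive at leading-edge maxima and negative at
  minima.  Everything else in the delivery is untouched.
* **Systematic leaf offset**, multiplicative image noise, and column
  "pixilation" lines (applied at render time only, under an explicit seed).

## Detector model and rendering

Fluence is accumulated in the gantry frame (the EPID and the diode array
are gantry-mounted) as MU-weighted open time on a pixel grid: per time
interval, `ΔMU × fractional coverage` of each pixel by the binary aperture
(leaf pair ∩ backup-jaw window), with intervals aligned to every trajectory
breakpoint and a default dt of 0.01 s.  The EPID grid is 0.256 mm at
100 cm; the diode array renders on a 1 mm grid and is sampled with a small
square active aperture at 1 cm spacing.  A Gaussian "ideal optics" blur of
σ = 0.15 mm is applied by default: it makes the flat-topped 1 mm picket
maxima unique (the max-pixel peak rule then lands within half a pixel of
the programmed centre) while remaining well under a quarter of the picket
width, so half-height widths are unbiased — at σ = 0.3 mm the 1 mm strip
already reads 9 % wide because its blurred peak no longer reaches the
plateau.  Uniform sweeps agree with the closed form `DR × gap / v` to
better than 0.5 % at the default dt.

## Test constructions

* **Picket fence** — both banks sweep at 0.4 cm/s with a 5 mm gap (6 mm
  when intentional errors are present).  At each picket the leading leaf
  advances over the 1 mm strip at full speed and holds until back on
  schedule; the trailing leaf holds at the strip entrance and then advances
  at full speed.  The two manoeuvres sum to a constant extra open time
  `w (1/v − 1/v_max)` over exactly `[p, p + w]` — a rectangular fluence
  picket whose half-height width is the programmed strip width and whose
  centre is `p + w/2`, which is what makes sub-pixel recovery of the
  1.5 mm widening and 0.5 mm shift possible.
* **Speed-limit fields** — single-segment sweeps with
  `MU = DR_max · travel / v_max` (10 cm DMLC with 8 mm gap; 10 cm jaw
  translation; 180° arc).  The acceptance procedure searches the 0.1 MU
  grid for the smallest MU still delivered at the top bin and inverts the
  sweep relation; the MLC and gantry thresholds (50 and 300 MU) sit on the
  grid so 2.0 cm/s and 6.0 °/s are recovered exactly, while the jaw
  threshold (66.7 MU) carries the grid-granularity error bound
  `DR·d·res/MU² ≤ 0.005 cm/s`.
* **DR:GS strips** — a 3 cm slit dwells on each of eight strips while the
  gantry arcs through `θ_i = MU_strip · GS_i / DR_i` (12° per matched strip
  at 20 MU), translating between strips at `0.75 v_max` with DR max/8
  (2 s, 2.5 MU per move, `ΔMU/Δθ = 0.208 MU/° ≥ 0.1`).  A lead-in/out move
  of one strip width equalises the move contribution at every strip
  midpoint, so the noiseless normalised means are 100.0 % for all eight
  strips including the capped 1.2× pair.
* **MLC-speed:DR strips** — a rigid 8 mm gap translates at the machine
  constant `dx/dMU = v_max/DR_max`, 15 MU per 3 cm strip, constant gantry
  speed 3.125 °/s; 1.5 cm margins at either end extend the plateau to the
  open-field width used for normalisation.  The minimum 5 mm gap is
  refused here because it performs poorly at maximum leaf speed.
* **Reversal strips** — one continuous zig-zag whose turning points sit on
  the junctions −5.6, −1.6, 3.6, 7.6, 10.6 cm, giving traversal counts
  {1, 3, 5, 7, 5.5} (a continuous left-to-right path can only produce odd
  full counts; the final half traversal ends where the last strip's centre
  has accumulated exactly half a gap passage).  All strips run at
  `DR_max/2`; one plan per speed factor {1.0, 0.95, 0.90, 0.18}, the 0.18
  plan serving as the negligible-over-travel reference.
* **DR-change strips** — constant leaf speed (half maximum; 0.25 cm/s for
  the reference), dose rates stepping `1/32 … 1` with the extreme
  `1/32 ↔ 1` jump in the last two strips; the decrease variant reverses
  the sequence.
* **Utility fields** — 25 × 25 cm open fields per bin (normalisation),
  36/1000 MU static and 360° arc chamber fields (36 MU sits exactly on the
  MU-per-degree floor), and the gravity test: 1 cm gap over 23 cm at
  0.74 cm/s with the 180° arc finishing exactly with the sweep
  (5.79 ≈ 5.8 °/s), interior fluence `10 × 1/0.74 = 13.51` MU-units.

## Analyses

Profiles are cross-plane (leaf-travel) cuts averaged over an in-plane band;
per published practice the EPID strip analysis uses a half-leaf band 0.5 cm
above the axis with a 7-pixel (1.8 mm) moving average, junction analyses a
3-pixel (0.77 mm) average, and repeat-image pixilation spikes (>3 % against
both ±0.5 mm neighbours) are dropped before averaging.  Normalisation is
pointwise percent of an open field at the same dose rate, masked below 5 %
of the open-field maximum.

Picket peaks follow the published rule — the local maximum pixel, ties
flagged and broken toward smaller x — while error metrology interpolates
the half-prominence crossings of each picket for sub-pixel centres and
widths; a pair is flagged when width or position deviates from nominal by
the 0.05 cm tolerance, credited with half a pixel of measurement
resolution so a deviation exactly at tolerance cannot be missed through
granularity (clean pairs measure within ~0.003 cm, far from the threshold).

Junction analyses measure against locally fitted baselines because the MU
of a low-dose-rate strip quantises visibly (a 0.94 MU strip entered as
0.9 MU is 4 % light — a real effect of the 0.1 MU entry grid, shared by
the hardware).  Reversal junctions integrate the excess area over
per-side linear baselines; with the aperture gap, the junction's net
signed turn count (opposite-sign reversals at one junction cancel) and the
local fluence level in gap-passage units, the over-travel comes back from
`area = net · δ² / (gap · level)`.  The area, unlike the peak, survives
pixelisation and smoothing, which is how 0.1 mm of over-travel is
recovered from 0.256 mm pixels.  Dose-rate-change junctions report the
longest `|excess| > 2 %/3 %` run and the settle distance past the
junction.  Chamber and imager-centre reports are plain ratio/deviation
arithmetic over grouped readings.

When comparing a fast delivery to its slow reference, the test suite
samples the reference with dt scaled by the speed ratio so both traces
step the leaves through the same positions and the discretisation error
cancels in the ratio.

## What the synthetic data does and does not show

The simulator is an ideal fluence integrator: no scatter, leaf
transmission, tongue-and-groove, energy response, beam profile, or gantry
inertia (exposed as a parameter, not calculated), and dose rates/energies
enter only as configuration.  Passing tests therefore demonstrate that the
*constructions and analyses* are mutually consistent and that injected
delivery errors of the published magnitudes are recoverable — not that any
physical machine meets tolerance.  The published hardware numbers
(actual-DR tables, measured strip means of 98–101 %, per-reversal
overdose rates) are instrument-specific and are deliberately not
reproduction targets; desk-scale derived quantities (bin tables, sweep-MU
values, smoothing windows, chamber ratios, picket aggregates) are.

## Numerical choices

dt = 0.01 s default (0.004 s in the reversal analyses), event-aligned
sub-steps at every control point, bin change and excursion breakpoint;
round-half-up MU quantisation at 0.1 MU; feasibility comparisons with a
1e-9 relative slack so speeds exactly at a limit are legal; normalisation
floor 5 %; peak ties broken toward smaller x and reported; strip ramp
segments excluded from analysis windows.  All randomness (noise,
pixilation, error placement) flows from explicit integer seeds; noiseless
renders are bitwise deterministic.
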