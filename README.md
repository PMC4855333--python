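# fptmigrate

Objective migration timing from animal relocation data, for movement
ecologists working with satellite-tracked migrants whose seasonal ranges
shift from year to year (the motivating case is migratory caribou, *Rangifer
tarandus*). When ranges move, geographic boundaries cannot define departure
and arrival dates; `fptmigrate` instead detects the *changes in movement
pattern* that bracket the spring migration: the end of the long winter pause
and the start of the short calving-ground pause.

## Method

**First-passage time (FPT).** For a circle of radius *r* centred on a path
point, FPT is the time the animal takes to cross the circle through its
centre (backward + forward passage time). Slow, tortuous area-restricted
search gives high FPT; directed travel gives low FPT. The working radius
*r*<sub>max</sub> is the peak of the mean S(r) = Var[log fpt(r)] curve
across annual paths (≈25 km at caribou scale).

**Penalized-contrast segmentation.** The FPT profile y is cut into K bouts
of homogeneous mean by exactly minimizing the within-bout sum of squares
J(τ, y) via dynamic programming for every K ≤ Kmax (default 30, minimum
bout length l<sub>min</sub> = 1). K* is selected where the rescaled
contrast curve's discrete second derivative last exceeds S = 0.75 — no
prior knowledge of the number of bouts is needed.

**Two-step detection.** Winter breaks (high-FPT bouts touching Dec–Apr) are
found on the whole multi-year profile, with a per-year fallback pass for
weak winters; each inter-winter slice is then re-segmented alone to resolve
the smaller June pause. Departure = end of the winter break (or of a
pre-migration pause directly after it); arrival = start of the June break,
optionally confirmed against a calving-ground GeoJSON polygon when the FPT
signal is equivocal.

**Validation.** A correlated-random-walk simulator generates labeled paths
(two designs: two long seasonal breaks, or one long + one short; log-normal
speeds 15/3 km/day, wrapped-Cauchy turning 0.8/0.1, reflecting patches of
50/25 km, 12-h steps) on which success and precision of the segmentation
are scored against ground truth.

## Worked example

```python
from fptmigrate import SimConfig, simulate_path, compute_fpt, process_profile

sim = simulate_path(SimConfig(path_type="2LB", seed=3))   # labeled 1000-point path
profile = compute_fpt(sim.path, r=25.0)                   # FPT profile, days
events, records = process_profile(profile)                # two-step detection
```

Iterating over `events` and `records` prints:

```
winter   2004-02-20 -> 2004-04-26  mean FPT  86.2 d  complete=False  route=whole_path
winter   2004-09-19 -> 2004-12-30  mean FPT  77.1 d  complete=True   route=whole_path
calving  2004-06-12 -> 2004-08-04  mean FPT  53.1 d  complete=True   route=whole_path
migration 2004: departure 2004-04-26, arrival 2004-06-12, complete=True
migration 2004: departure 2004-12-30, arrival None, complete=False
```

Reading it: the two long simulated breaks are recovered as winter pauses
(the first is `complete=False` because the path *starts* inside it, so its
onset was never observed; mean FPT ≈ 86 days reflects a circle the walker
barely leaves). The first stopover, which the simulation places in June, is
recovered as the calving pause, giving a complete spring migration:
departure 26 Apr, arrival 12 Jun — within ~2 days of the true simulated
boundaries (24 Apr / 13 Jun). The second record is open-ended: the path
stops before the next June.

The same chain runs from the shell on delimited tracks
(`id,timestamp,x_km,y_km[,quality]`; projected km):

```
fpt-migrate simulate --type 2LB --n 1 --seed 3 --out-dir sim/
fpt-migrate run --tracks tracks.csv --radius 25 --lmin 1 --kmax 30 \
    --sthresh 0.75 --out-dir out/        # writes break_events.csv,
                                         # migration_records.csv, run_config.json
fpt-migrate table1 --n 50 --seed 1      # the full simulation validation
```

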