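# unitfinder

Untargeted detection of repeating chemical units ("changing units") in
high-resolution mass spectrometry peak lists.

Polymeric and other homologous series appear in a spectrum as arithmetic
progressions in m/z with a fixed repeat-unit mass (e.g. C2H4O for PEG, CF2
for perfluorinated compounds, C3H6O for PPG). `unitfinder`:

1. **Generates a formula library** by systematic iteration over
   C, H, S, O, N, P, F, Cl, Br, Si and a massless valence-1 placeholder `X`
   that marks the unit's connection points to its molecular scaffold. Each
   valence state of S (2/4/6) and P (3/5) is iterated independently, and
   candidates are validated with a restricted double-bond-equivalent (DBE)
   criterion that rejects under-/over-bonded compositions such as NX.
2. **Screens the library** with per-element count limits, per-carbon
   elemental ratio bounds (0.3 ≤ H/C ≤ 4.0, …, 0 ≤ Si/C ≤ 0.5), a unit-mass
   window (14–200 Da by default) and a DBE ceiling. In untargeted mode the
   upper mass bound is capped at max(m/z) / (minimum desired repetitions).
3. **Detects repeating units** with two algorithms:
   * **local search** — requires sequential chains `p, p+u, …, p+m·u`
     within the spectrum (theoretical-sum chaining, so mass errors do not
     accumulate);
   * **global search** — requires every multiple `k·u` (k = 1…m) to appear
     in the multiset of all pairwise peak differences, with no locality
     constraint (the default for untargeted runs).
4. Provides **Kendrick mass defect** transforms, peak-list **data filters**
   (top-N by intensity, relative intensity threshold), and a deterministic
   **synthetic spectrum generator** with planted series for testing.

## CLI

```sh
# enumerate + validate + screen a library (restricted example)
unitfinder build-library --out lib.csv --only-elements C,H,O,F,X \
    --limit C=0-4 --limit H=0-10 --limit O=0-2 --limit F=0-3

# simulate a spectrum with a planted PEG ladder and noise
unitfinder simulate --out peaks.csv --series C2H4O,150.0,0,6 \
    --seed 5 --n-noise 20 --manifest truth.json

# untargeted unit finding (global search, auto criteria)
unitfinder find-units --input peaks.csv --library lib.csv --out hits.csv

# targeted run: local search, custom repetition count and tolerances
unitfinder find-units --input peaks.csv --library lib.csv --out hits.csv \
    --mode targeted --algorithm local -m 2 --selection-error 0.002 \
    --loop-error 0.002 --top-n 988

# Kendrick table for a unit given by formula or literal mass
unitfinder kmd --input peaks.csv --unit C2H4O --out kmd.csv
```

Peak lists are two-column delimited text (m/z in Da, intensity); comma, tab,
semicolon and whitespace dialects are auto-detected, one header row is
skipped, duplicate m/z rows are merged. Omitting `--library` enumerates the
full default library (~3.9 M formulas, ~54 k candidates after screening);
pass a restricted library for fast runs.

Exit codes: 0 success (including empty hit lists), 1 usage error, 2 data
error, 3 `build-library` produced no candidates.

## Python API

```python
import numpy as np
from unitfinder import (
    SearchConfig, UnitCandidate, find_units, generate_spectrum, SeriesSpec,
)

peg = UnitCandidate.from_formula("C2H4O")
peaks = generate_spectrum([SeriesSpec(peg, 150.0, 0, 6)], n_noise=20, seed=1)
hits = find_units(peaks, SearchConfig(mode="untargeted"))
```

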