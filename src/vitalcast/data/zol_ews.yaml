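# Early-warning-score component thresholds, Ziekenhuis Oost-Limburg (ZOL)
# convention.  Bands are closed intervals on the vital's resolution grid;
# null bounds are open ends.  Where a printed boundary value belongs to two
# adjacent bands (SBP 180), the lower band wins, so it is listed first.
# The temperature row is shipped for completeness but flagged unused: the
# wearable device carries no temperature sensor.
vitals:
  HR:
    unit: BPM
    resolution: 1
    bands:
      - {lo: null, hi: 39, score: 2}
      - {lo: 40, hi: 50, score: 1}
      - {lo: 51, hi: 100, score: 0}
      - {lo: 101, hi: 110, score: 1}
      - {lo: 111, hi: 130, score: 2}
      - {lo: 131, hi: null, score: 3}
  RR:
    unit: BPM
    resolution: 1
    bands:
      - {lo: null, hi: 8, score: 2}
      - {lo: 9, hi: 14, score: 0}
      - {lo: 15, hi: 20, score: 1}
      - {lo: 21, hi: 30, score: 2}
      - {lo: 31, hi: null, score: 3}
  SpO2:
    unit: "%"
    resolution: 1
    bands:
      - {lo: null, hi: 90, score: 3}
      - {lo: 91, hi: 93, score: 2}
      - {lo: 94, hi: 95, score: 1}
      - {lo: 96, hi: null, score: 0}
  SBP:
    unit: mmHg
    resolution: 1
    bands:
      - {lo: null, hi: 69, score: 3}
      - {lo: 70, hi: 80, score: 2}
      - {lo: 81, hi: 100, score: 1}
      - {lo: 101, hi: 180, score: 0}
      - {lo: 180, hi: 200, score: 1}
      - {lo: 201, hi: null, score: 2}
  Temperature:
    unit: degC
    resolution: 0.1
    unused: true
    bands:
      - {lo: null, hi: 35.0, score: 2}
      - {lo: 35.1, hi: 36.5, score: 1}
      - {lo: 36.6, hi: 37.5, score: 0}
      - {lo: 37.6, hi: null, score: 1}
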