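"""Frozen-oracle generator: NOAA solar-calculator spreadsheet algorithm.

Transcribed cell-by-cell from the NOAA Solar Calculation spreadsheet
(sunrise/sunset version), independently of the package implementation.
Regenerates the reference table tests/data/sunset_oracle.csv.
"""
import math
import csv
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "tests" / "data" / "sunset_oracle.csv"


def julian_day(d: date) -> float:
    # JD at 0h UT for a civil date
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def sunset_utc_minutes(d: date, lat: float, lon: float) -> float:
    """Minutes past 00:00 UTC of sunset on civil date d (may exceed 1440)."""
    # iterate: NOAA spreadsheet uses local time-of-day in the Julian century;
    # two passes converge to well under a second
    tod = 0.5  # fraction of day, first guess noon UT
    for _ in range(4):
        jd = julian_day(d) + tod
        t = (jd - 2451545.0) / 36525.0
        geom_mean_long = (280.46646 + t * (36000.76983 + t * 0.0003032)) % 360.0
        geom_mean_anom = 357.52911 + t * (35999.05029 - 0.0001537 * t)
        ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
        m = math.radians(geom_mean_anom)
        eq_ctr = (math.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
                  + math.sin(2 * m) * (0.019993 - 0.000101 * t)
                  + math.sin(3 * m) * 0.000289)
        true_long = geom_mean_long + eq_ctr
        omega = 125.04 - 1934.136 * t
        app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
        mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
        obliq_corr = mean_obliq + 0.00256 * math.cos(math.radians(omega))
        decl = math.degrees(math.asin(math.sin(math.radians(obliq_corr))
                                      * math.sin(math.radians(app_long))))
        var_y = math.tan(math.radians(obliq_corr / 2.0)) ** 2
        l0 = math.radians(geom_mean_long)
        eq_time = 4.0 * math.degrees(
            var_y * math.sin(2 * l0)
            - 2 * ecc * math.sin(m)
            + 4 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
            - 0.5 * var_y ** 2 * math.sin(4 * l0)
            - 1.25 * ecc ** 2 * math.sin(2 * m))
        cos_ha = (math.cos(math.radians(90.833))
                  / (math.cos(math.radians(lat)) * math.cos(math.radians(decl)))
                  - math.tan(math.radians(lat)) * math.tan(math.radians(decl)))
        ha = math.degrees(math.acos(max(-1.0, min(1.0, cos_ha))))
        solar_noon_utc_min = 720.0 - 4.0 * lon - eq_time  # minutes past 0h UT
        sunset_min = solar_noon_utc_min + 4.0 * ha
        tod = sunset_min / 1440.0
    return sunset_min


def main():
    rows = []
    # in-domain grid: Aug-Oct dates x 41-44N, study-region longitude
    lats = [41.0, 42.0, 43.0, 44.0]
    d0 = date(2017, 8, 1)
    n = 0
    while n < 365:
        d = d0 + timedelta(days=n % 92)
        lat = lats[(n // 92) % 4]
        lon = -80.4877 + 0.5 * ((n * 7) % 11 - 5)  # spread lon a bit in-domain
        mins = sunset_utc_minutes(d, lat, lon)
        ts = datetime(d.year, d.month, d.day, tzinfo=timezone.utc) + timedelta(minutes=mins)
        rows.append((d.isoformat(), f"{lat:.4f}", f"{lon:.4f}",
                     ts.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"))
        n += 1
    # spot checks used in unit tests
    for (d, lat, lon) in [(date(2016, 9, 19), 42.6914, -80.4877),
                          (date(2017, 9, 22), 0.0, 0.0),
                          (date(2018, 10, 15), 41.0, -81.0)]:
        mins = sunset_utc_minutes(d, lat, lon)
        ts = datetime(d.year, d.month, d.day, tzinfo=timezone.utc) + timedelta(minutes=mins)
        rows.append((d.isoformat(), f"{lat:.4f}", f"{lon:.4f}",
                     ts.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"))
        print(d, lat, lon, "->", ts.isoformat())
    with open(OUT, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "lat", "lon", "sunset_utc"])
        w.writerows(rows)
    print(len(rows), "rows frozen")


if __name__ == "__main__":
    main()
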