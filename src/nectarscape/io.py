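"""Plain-text I/O: curve CSVs, composition tables, ESRI ASCII grids, YAML.

Rasters travel as ESRI ASCII grids (a self-describing plain-text format
readable by any GIS); tables as CSV; model configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nectarscape.phenology import PhenologyCurve
from nectarscape.synthetic import LandcoverRaster, Landscape


def write_curve(curve: PhenologyCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_curve(path, habitat: str | None = None) -> PhenologyCurve:
    df = pd.read_csv(path)
    name = habitat or Path(path).stem
    return PhenologyCurve(
        name, df["day"].to_numpy(), df["value"].to_numpy(), df["se"].to_numpy()
    )


def write_landscape(ls: Landscape, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    comp = pd.DataFrame(
        {"habitat": list(ls.areas), "area_m2": list(ls.areas.values())}
    )
    comp["landscape_id"] = ls.landscape_id
    comp["cell_area_m2"] = ls.cell_area
    comp.to_csv(d / f"{ls.landscape_id}_composition.csv", index=False)
    ls.patches.to_csv(d / f"{ls.landscape_id}_patches.csv", index=False)


def read_landscape(directory, landscape_id: str) -> Landscape:
    d = Path(directory)
    comp = pd.read_csv(d / f"{landscape_id}_composition.csv")
    patches = pd.read_csv(d / f"{landscape_id}_patches.csv")
    areas = dict(zip(comp["habitat"], comp["area_m2"]))
    return Landscape(
        landscape_id, areas, float(comp["cell_area_m2"].iloc[0]), patches
    )


def write_ascii_grid(raster: LandcoverRaster, path) -> None:
    """ESRI ASCII grid (plain text)."""
    rows, cols = raster.grid.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {raster.resolution}\nNODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%d")


def read_ascii_grid(path, class_map: dict[int, str] | None = None) -> LandcoverRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) == 2 and not line[0].lstrip("-").replace(".", "").isdigit():
                header[line[0].lower()] = float(line[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        grid = np.loadtxt(fh, dtype=np.int32)
    grid = grid.reshape(int(header["nrows"]), int(header["ncols"]))
    from nectarscape.synthetic import CLASS_CODES

    return LandcoverRaster(
        grid,
        float(header.get("cellsize", 1.0)),
        class_map or dict(CLASS_CODES),
        int(header.get("nodata_value", -9999)),
    )


def read_class_map(path) -> dict[int, str]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {int(k): str(v) for k, v in raw.items()}
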