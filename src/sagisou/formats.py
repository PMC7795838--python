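"""Genepop and STRUCTURE text round-tripping, plus contour/landmark CSV.

Genepop dialect: title line, locus names (comma-separated or one per line),
``Pop`` separators, then ``name ,  aaabbb aaabbb ...`` individual lines in
the 3-digit (default) or 2-digit allele encoding, auto-detected from token
width on read; ``000``/``00`` is the missing code.  The format carries no
explicit population names, so on read they are inferred from each Pop
block's last individual label with trailing digits/separators stripped —
the one place population identity is inferred rather than carried
explicitly.

STRUCTURE dialect: one row per individual (two columns per locus) or two
rows per individual (one column per locus), tab-separated with a locus
header row, ``-9`` missing.  The population column holds the population
label; labels that are integers match what STRUCTURE itself expects.
Readers reject malformed input with the offending line number rather than
repairing it.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset
from .morphometrics import Contour, LipAnnotation

__all__ = [
    "read_genepop", "write_genepop",
    "read_structure", "write_structure",
    "write_contours", "read_contours",
    "write_landmarks", "read_landmarks",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def _infer_pop_name(label: str) -> str:
    stripped = label.rstrip("0123456789").rstrip("_-. \t")
    return stripped or label


def read_genepop(path) -> GenotypeDataset:
    """Parse a Genepop file (2- or 3-digit dialect auto-detected)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: too short for a Genepop file")
    # locus names: lines 1.. until the first Pop separator
    loci: list[str] = []
    first_pop = None
    for ln, raw in enumerate(lines[1:], start=2):
        if _POP_RE.match(raw.strip()):
            first_pop = ln
            break
        for name in raw.split(","):
            name = name.strip()
            if name:
                loci.append(name)
    if first_pop is None:
        raise FormatError(f"{path}: no 'Pop' separator found")
    if not loci:
        raise FormatError(f"{path}: no locus names before the first 'Pop'")

    digits = None
    pop_blocks: list[list[tuple[str, list[int]]]] = []
    current: list[tuple[str, list[int]]] | None = None
    for ln, raw in enumerate(lines[first_pop - 1:], start=first_pop):
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            current = []
            pop_blocks.append(current)
            continue
        if current is None:
            raise FormatError(f"{path}:{ln}: genotype line before any 'Pop'")
        if "," not in line:
            raise FormatError(f"{path}:{ln}: expected 'name , genotypes'")
        name, _, geno = line.partition(",")
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise FormatError(
                f"{path}:{ln}: {len(tokens)} genotype tokens for {len(loci)} loci"
            )
        calls = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise FormatError(f"{path}:{ln}: bad genotype token {tok!r}")
            w = len(tok) // 2
            if digits is None:
                digits = w
            elif w != digits:
                raise FormatError(
                    f"{path}:{ln}: mixed {2 * digits}- and {len(tok)}-char tokens"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            if (a1 == 0) != (a2 == 0):
                raise FormatError(f"{path}:{ln}: half-missing genotype {tok!r}")
            calls.append([a1 or MISSING, a2 or MISSING])
        current.append((name, calls))

    if any(not block for block in pop_blocks):
        raise FormatError(f"{path}: empty Pop block")

    pop_names: list[str] = []
    for block in pop_blocks:
        name = _infer_pop_name(block[-1][0])
        while name in pop_names:
            name += "_dup"
        pop_names.append(name)

    individuals, pop_index, call_rows = [], [], []
    for p, block in enumerate(pop_blocks):
        for name, calls in block:
            individuals.append(name)
            pop_index.append(p)
            call_rows.append(calls)
    return GenotypeDataset(
        populations=pop_names,
        pop_index=np.asarray(pop_index),
        individuals=individuals,
        loci=loci,
        calls=np.asarray(call_rows),
    )


def write_genepop(dataset: GenotypeDataset, path, digits: int = 3,
                  title: str = "sagisou export") -> None:
    """Write the canonical Genepop dialect (3-digit default)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10 ** digits - 1
    for l, locus in enumerate(dataset.loci):
        col = dataset.calls[:, l, :]
        valid = col[col != MISSING]
        if valid.size and valid.max() > limit:
            raise ValueError(
                f"allele {int(valid.max())} at locus {locus!r} does not fit "
                f"in {digits} digits"
            )
    out = [title]
    out += list(dataset.loci)
    for p in range(dataset.n_populations):
        out.append("Pop")
        for i in np.flatnonzero(dataset.pop_index == p):
            tokens = []
            for l in range(dataset.n_loci):
                a1, a2 = dataset.calls[i, l]
                a1 = 0 if a1 == MISSING else int(a1)
                a2 = 0 if a2 == MISSING else int(a2)
                tokens.append(f"{a1:0{digits}d}{a2:0{digits}d}")
            out.append(f"{dataset.individuals[i]} ,  " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE
# ---------------------------------------------------------------------------

_STRUCT_MISSING = "-9"


def write_structure(dataset: GenotypeDataset, path, two_rows: bool = False,
                    pop_column: bool = True) -> None:
    """Write STRUCTURE-format text (tab-separated, -9 missing)."""
    lines = ["\t".join(dataset.loci)]
    for i, ind in enumerate(dataset.individuals):
        prefix = [ind]
        if pop_column:
            prefix.append(dataset.populations[dataset.pop_index[i]])
        if two_rows:
            for copy in (0, 1):
                row = [
                    _STRUCT_MISSING if dataset.calls[i, l, copy] == MISSING
                    else str(int(dataset.calls[i, l, copy]))
                    for l in range(dataset.n_loci)
                ]
                lines.append("\t".join(prefix + row))
        else:
            row = []
            for l in range(dataset.n_loci):
                for copy in (0, 1):
                    v = dataset.calls[i, l, copy]
                    row.append(_STRUCT_MISSING if v == MISSING else str(int(v)))
            lines.append("\t".join(prefix + row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path, two_rows: bool = False,
                   pop_column: bool = True) -> GenotypeDataset:
    """Read STRUCTURE-format text written by :func:`write_structure`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: too short for a STRUCTURE file")
    loci = lines[0].split("\t")
    n_meta = 1 + (1 if pop_column else 0)
    expect = n_meta + (len(loci) if two_rows else 2 * len(loci))

    records: list[tuple[str, str, list[int]]] = []
    body = lines[1:]
    if two_rows:
        if len(body) % 2:
            raise FormatError(f"{path}: odd number of genotype rows")
        row_pairs = [(body[2 * i], body[2 * i + 1], 2 * i + 2) for i in range(len(body) // 2)]
        for top, bottom, ln in row_pairs:
            t, b = top.split("\t"), bottom.split("\t")
            if len(t) != expect or len(b) != expect:
                raise FormatError(f"{path}:{ln}: ragged row")
            if t[:n_meta] != b[:n_meta]:
                raise FormatError(f"{path}:{ln}: mismatched row pair labels")
            name = t[0]
            pop = t[1] if pop_column else "Pop1"
            flat: list[int] = []
            for a, b2 in zip(t[n_meta:], b[n_meta:]):
                flat += [int(a), int(b2)]
            records.append((name, pop, flat))
    else:
        for ln, raw in enumerate(body, start=2):
            t = raw.split("\t")
            if len(t) != expect:
                raise FormatError(f"{path}:{ln}: ragged row "
                                  f"({len(t)} fields, expected {expect})")
            name = t[0]
            pop = t[1] if pop_column else "Pop1"
            flat = [int(x) for x in t[n_meta:]]
            records.append((name, pop, flat))

    pops: list[str] = []
    pop_index, individuals, call_rows = [], [], []
    for name, pop, flat in records:
        if pop not in pops:
            pops.append(pop)
        pop_index.append(pops.index(pop))
        individuals.append(name)
        row = []
        for l in range(len(loci)):
            a1, a2 = flat[2 * l], flat[2 * l + 1]
            a1 = MISSING if a1 == int(_STRUCT_MISSING) else a1
            a2 = MISSING if a2 == int(_STRUCT_MISSING) else a2
            if (a1 == MISSING) != (a2 == MISSING):
                raise FormatError(
                    f"{path}: half-missing call for {name!r} at {loci[l]!r}"
                )
            row.append([a1, a2])
        call_rows.append(row)
    return GenotypeDataset(
        populations=pops,
        pop_index=np.asarray(pop_index),
        individuals=individuals,
        loci=loci,
        calls=np.asarray(call_rows),
    )


# ---------------------------------------------------------------------------
# contour / landmark CSV
# ---------------------------------------------------------------------------


def write_contours(annotations: dict[str, LipAnnotation], path) -> None:
    """Contour CSV: shape_id, role in {lip, left_wing}, vertex_index, x_mm, y_mm."""
    rows = []
    for shape_id, ann in annotations.items():
        for role, contour in (("lip", ann.lip_contour),
                              ("left_wing", ann.left_wing_contour)):
            for i, (x, y) in enumerate(contour.vertices):
                rows.append((shape_id, role, i, x, y))
    pd.DataFrame(rows, columns=["shape_id", "role", "vertex_index",
                                "x_mm", "y_mm"]).to_csv(path, index=False)


_LANDMARK_POINTS = ("body_base", "body_tip", "body_width_a", "body_width_b",
                    "wing_base", "wing_tip")


def write_landmarks(annotations: dict[str, LipAnnotation], path) -> None:
    """Landmark CSV: one row per shape with named landmark coordinates and
    the serrated-margin vertex range."""
    rows = []
    for shape_id, ann in annotations.items():
        pts = {
            "body_base": ann.body_base, "body_tip": ann.body_tip,
            "body_width_a": ann.body_width_segment[0],
            "body_width_b": ann.body_width_segment[1],
            "wing_base": ann.wing_base, "wing_tip": ann.wing_tip,
        }
        row: dict = {"shape_id": shape_id}
        for name in _LANDMARK_POINTS:
            row[f"{name}_x"] = pts[name][0]
            row[f"{name}_y"] = pts[name][1]
        row["margin_start"], row["margin_stop"] = ann.serrated_margin
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours(path) -> dict[str, dict[str, np.ndarray]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, np.ndarray]] = {}
    for (shape_id, role), grp in df.groupby(["shape_id", "role"], sort=False):
        grp = grp.sort_values("vertex_index")
        out.setdefault(str(shape_id), {})[str(role)] = grp[["x_mm", "y_mm"]].to_numpy()
    return out


def read_landmarks(path) -> dict[str, dict]:
    df = pd.read_csv(path)
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        out[str(row["shape_id"])] = {
            name: np.array([row[f"{name}_x"], row[f"{name}_y"]])
            for name in _LANDMARK_POINTS
        } | {"margin": (int(row["margin_start"]), int(row["margin_stop"]))}
    return out


def load_annotations(contour_path, landmark_path) -> dict[str, LipAnnotation]:
    """Reassemble LipAnnotations from the contour + landmark CSV pair."""
    contours = read_contours(contour_path)
    landmarks = read_landmarks(landmark_path)
    out: dict[str, LipAnnotation] = {}
    for shape_id, parts in contours.items():
        if shape_id not in landmarks:
            raise FormatError(f"no landmarks for shape {shape_id!r}")
        lm = landmarks[shape_id]
        out[shape_id] = LipAnnotation(
            lip_contour=Contour(parts["lip"], closed=True),
            left_wing_contour=Contour(parts["left_wing"], closed=True),
            body_base=lm["body_base"],
            body_tip=lm["body_tip"],
            body_width_segment=(lm["body_width_a"], lm["body_width_b"]),
            wing_base=lm["wing_base"],
            wing_tip=lm["wing_tip"],
            serrated_margin=lm["margin"],
        )
    return out
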