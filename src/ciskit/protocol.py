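"""Protocol scripts: record, parse, and replay complete workflows.

A protocol is a linear list of statements, one operation each::

    # promoter scan
    bg      = train_background dna=dna order=3
    sites   = scan_motifs dna=dna motifs=lib threshold=0.8
    kept    = filter_regions track=sites where avg(conservation) >= 0.3

Each statement stores its result in the repository under the target
name.  Values are numbers, quoted strings, or bare names; a bare name
that matches a repository object is resolved to that object at run
time.  There is no control flow — a protocol is a reproducible linear
record, replayable on other data and other seeds.

Randomized operations draw per-statement seeds derived from one master
seed by hashing (statement index, target name), so inserting a
statement does not reshuffle unrelated downstream randomness.

The generic external-tool adapter runs any command-line program
described by a small XML config declaring its command template, file
slots and parameters; inputs are serialized to declared formats,
outputs parsed back into data objects.
"""

from __future__ import annotations

import os
import re
import shlex
import shutil
import subprocess
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from . import analysis, modules, motifs as motif_ops, ops, priors as priors_ops
from .conditions import parse_condition
from .core import (CiskitError, Collection, DNATrack, GenomicSequence,
                   MotifCollectionObj, NumericMap, NumericTrack, RegionTrack,
                   Repository, SequenceSet, TextVariable, is_identifier)
from . import io as track_io


# ---------------------------------------------------------------- statements

@dataclass
class Statement:
    target: str
    operation: str
    args: List[Tuple[str, Tuple[str, object]]]  # (arg name, (kind, value))
    where: Optional[str] = None
    line: int = 0

    def serialize(self) -> str:
        parts = [f"{self.target} = {self.operation}"]
        for name, (kind, value) in self.args:
            if kind == "num":
                parts.append(f"{name}={value!r}")
            elif kind == "name":
                parts.append(f"{name}={value}")
            else:
                parts.append(f'{name}="{value}"')
        text = " ".join(parts)
        if self.where:
            text += f" where {self.where}"
        return text


@dataclass
class ProtocolScript:
    statements: List[Statement] = field(default_factory=list)
    lines: List[str] = field(default_factory=list)  # original text incl. comments

    def serialize(self) -> str:
        return "\n".join(s.serialize() for s in self.statements) + "\n"


_STMT_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*=\s*([A-Za-z_][A-Za-z0-9_]*)\s*(.*)$")
_ARG_RE = re.compile(r"""([A-Za-z_][A-Za-z0-9_]*)\s*=\s*("[^"]*"|[^\s]+)""")
_NUM_RE = re.compile(r"^-?\d+\.?\d*(?:[eE][-+]?\d+)?$")


def parse_protocol(text: str) -> ProtocolScript:
    """Parse protocol source; errors carry the line number."""
    script = ProtocolScript(lines=text.splitlines())
    defined = set()
    for lineno, raw in enumerate(script.lines, 1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        m = _STMT_RE.match(line)
        if not m:
            col = len(line) - len(line.lstrip()) + 1
            raise CiskitError(f"protocol syntax error at line {lineno}, column {col}: "
                              f"expected 'target = operation ...'")
        target, opname, rest = m.groups()
        where = None
        if " where " in f" {rest} ":
            rest, where = re.split(r"\bwhere\b", rest, maxsplit=1)
            where = where.strip()
            parse_condition(where)  # validate eagerly, error with line below
        args: List[Tuple[str, Tuple[str, object]]] = []
        consumed = 0
        for am in _ARG_RE.finditer(rest):
            consumed += len(am.group(0))
            name, value = am.group(1), am.group(2)
            if value.startswith('"'):
                args.append((name, ("str", value[1:-1])))
            elif _NUM_RE.match(value):
                num = float(value)
                args.append((name, ("num", int(num) if num.is_integer() and
                                    "." not in value and "e" not in value.lower()
                                    else num)))
            else:
                if not is_identifier(value):
                    raise CiskitError(
                        f"protocol syntax error at line {lineno}: bad value {value!r}")
                args.append((name, ("name", value)))
        if rest.strip() and consumed == 0:
            col = line.find(rest.strip()) + 1
            raise CiskitError(f"protocol syntax error at line {lineno}, column {col}: "
                              f"arguments must be name=value")
        for _, (kind, value) in args:
            if kind == "name" and value not in defined and value not in _BARE_WORDS:
                # bare names may also refer to pre-registered objects; defer to
                # execution when they are plainly option-like words
                pass
        script.statements.append(Statement(target, opname, args, where, lineno))
        defined.add(target)
    return script


# option-like bare words that never name repository objects
_BARE_WORDS = {"true", "false", "mean", "median", "min", "max", "sum", "both",
               "forward", "coverage", "max_score", "gc_content", "length",
               "count_base", "add", "sub", "mul", "div", "log", "range_normalize",
               "tss", "sequence_end", "bonferroni", "none", "ascending",
               "descending", "extend", "merge", "N", "X", "A", "C", "G", "T",
               "psp", "fasta", "gff", "bed", "wig", "bedgraph", "jaspar",
               "transfac", "meme", "html", "raw", "TSS", "TES"}


def derive_seed(master_seed: int, index: int, target: str) -> int:
    """Per-statement seed: stable hash of (index, target) mixed with the
    master seed, kept below 2^31."""
    h = zlib.crc32(f"{index}:{target}".encode())
    return (int(master_seed) * 1000003 + h) % (2 ** 31)


# ----------------------------------------------------------------- execution

class _Env:
    def __init__(self, repo: Repository, seed: int):
        self.repo = repo
        self.seed = seed

    def value(self, kindval):
        kind, value = kindval
        if kind == "name":
            if value == "true":
                return True
            if value == "false":
                return False
            if value in self.repo:
                return self.repo.get(value)
            return value  # option word
        return value

    def kwargs(self, stmt: Statement) -> Dict[str, object]:
        return {name: self.value(kv) for name, kv in stmt.args}


OpFunc = Callable[..., object]
_REGISTRY: Dict[str, OpFunc] = {}


def operation(name: str):
    def deco(fn):
        _REGISTRY[name] = fn
        return fn
    return deco


def registered_operations() -> List[str]:
    return sorted(_REGISTRY)


def execute_protocol(script: ProtocolScript, repo: Repository,
                     seed: int = 0) -> Tuple[Repository, List[dict]]:
    """Replay a protocol on a copy of the repository.

    Returns (new repository, run log).  Any failing statement aborts the
    run; the input repository is never modified.
    """
    work = repo.copy()
    log: List[dict] = []
    for index, stmt in enumerate(script.statements):
        if stmt.operation not in _REGISTRY:
            raise CiskitError(f"line {stmt.line}: unknown operation {stmt.operation!r}")
        env = _Env(work, derive_seed(seed, index, stmt.target))
        try:
            result = _REGISTRY[stmt.operation](env, stmt)
        except Exception as exc:
            raise CiskitError(f"line {stmt.line} ({stmt.target} = "
                              f"{stmt.operation}): {exc}") from exc
        work.put(stmt.target, result)
        log.append({"line": stmt.line, "target": stmt.target,
                    "operation": stmt.operation,
                    "args": {k: v for k, (_, v) in
                             [(n, kv) for n, kv in stmt.args]},
                    "seed": env.seed})
    return work, log


# ----------------------------------------------------------------- recording

class Workbench:
    """Repository plus protocol recorder.

    ``do(target, operation, where=..., **args)`` executes one operation
    (argument values written exactly as in protocol syntax: numbers,
    bare repository names, or strings) and, while recording is on,
    appends the canonical statement.  ``record('start'/'stop')`` toggles
    recording; stop returns the protocol text.
    """

    def __init__(self, repo: Optional[Repository] = None, seed: int = 0):
        self.repo = repo if repo is not None else Repository()
        self.seed = seed
        self._recording: Optional[List[Statement]] = None
        self._counter = 0

    def record(self, switch: str):
        if switch == "start":
            self._recording = []
            self._counter = 0  # statement indices restart so replay seeds match
            return None
        if switch == "stop":
            if self._recording is None:
                raise CiskitError("recording was never started")
            script = ProtocolScript(statements=self._recording)
            self._recording = None
            return script.serialize()
        raise CiskitError("record switch must be 'start' or 'stop'")

    def do(self, target: str, operation: str, where: Optional[str] = None, **args):
        stmt_args: List[Tuple[str, Tuple[str, object]]] = []
        for name, value in args.items():
            if isinstance(value, bool):
                stmt_args.append((name, ("name", "true" if value else "false")))
            elif isinstance(value, (int, float)):
                stmt_args.append((name, ("num", value)))
            elif isinstance(value, str) and is_identifier(value):
                stmt_args.append((name, ("name", value)))
            else:
                stmt_args.append((name, ("str", str(value))))
        stmt = Statement(target, operation, stmt_args, where)
        if operation not in _REGISTRY:
            raise CiskitError(f"unknown operation {operation!r}")
        env = _Env(self.repo, derive_seed(self.seed, self._counter, target))
        result = _REGISTRY[operation](env, stmt)
        self.repo.put(target, result)
        self._counter += 1
        if self._recording is not None:
            self._recording.append(stmt)
        return result


def record_protocol(workbench: Workbench, switch: str):
    return workbench.record(switch)


# -------------------------------------------------------- operation registry

def _cond(env: _Env, stmt: Statement):
    return parse_condition(stmt.where) if stmt.where else None


def _seed_arg(env: _Env, kwargs: Dict[str, object]) -> int:
    return int(kwargs.pop("seed", env.seed))


@operation("new_sequences")
def _op_new_sequences(env, stmt):
    kw = env.kwargs(stmt)
    n = int(kw.get("n", 1))
    length = int(kw["length"])
    prefix = kw.get("prefix", stmt.target)
    return SequenceSet(GenomicSequence(f"{prefix}_{i + 1}", f"{prefix}_{i + 1}",
                                       0, length) for i in range(n))


@operation("train_background")
def _op_train_background(env, stmt):
    kw = env.kwargs(stmt)
    return motif_ops.train_background(kw["dna"], int(kw.get("order", 0)))


@operation("sample_dna")
def _op_sample_dna(env, stmt):
    kw = env.kwargs(stmt)
    seed = _seed_arg(env, kw)
    model = kw["background"]
    n = int(kw.get("n", 1))
    length = int(kw["length"])
    prefix = kw.get("prefix", stmt.target)
    seqs = SequenceSet(GenomicSequence(f"{prefix}_{i + 1}", f"{prefix}_{i + 1}",
                                       0, length) for i in range(n))
    data = {s.name: motif_ops.sample_background(model, length, seed + i)
            for i, s in enumerate(seqs)}
    return DNATrack(seqs, data)


@operation("scan_motifs")
def _op_scan_motifs(env, stmt):
    kw = env.kwargs(stmt)
    return motif_ops.scan_motifs(kw["dna"], kw["motifs"], float(kw["threshold"]),
                                 background=kw.get("background"),
                                 strands=kw.get("strands", "both"))


@operation("match_consensus")
def _op_match_consensus(env, stmt):
    kw = env.kwargs(stmt)
    return motif_ops.match_consensus(kw["dna"], kw["pattern"],
                                     kw.get("strands", "both"))


@operation("mask")
def _op_mask(env, stmt):
    kw = env.kwargs(stmt)
    seed = _seed_arg(env, kw)
    where = kw.pop("regions", None) or _cond(env, stmt)
    return ops.mask(kw["dna"], kw.get("fill", "N"), where, seed=seed, env=env.repo)


@operation("filter_regions")
def _op_filter_regions(env, stmt):
    kw = env.kwargs(stmt)
    cond = _cond(env, stmt)
    if cond is None:
        raise CiskitError("filter_regions requires a where condition")
    return ops.filter_regions(kw["track"], cond, env=env.repo)


@operation("extend_regions")
def _op_extend(env, stmt):
    kw = env.kwargs(stmt)
    return ops.extend_regions(kw["track"], int(kw.get("up", 0)),
                              int(kw.get("down", 0)),
                              bool(kw.get("strand_aware", False)))


@operation("merge_regions")
def _op_merge(env, stmt):
    kw = env.kwargs(stmt)
    return ops.merge_regions(kw["track"], int(kw.get("max_gap", 0)))


@operation("arithmetic")
def _op_arithmetic(env, stmt):
    kw = env.kwargs(stmt)
    target = None
    if "lo" in kw or "hi" in kw:
        target = (float(kw.pop("lo", 0.0)), float(kw.pop("hi", 1.0)))
    return ops.arithmetic(kw["track"], kw["op"], kw.get("operand"),
                          where=_cond(env, stmt), env=env.repo, target=target)


@operation("sliding_window")
def _op_window(env, stmt):
    kw = env.kwargs(stmt)
    return ops.sliding_window(kw["track"], kw.get("stat", "mean"),
                              int(kw.get("size", 3)))


@operation("combine_tracks")
def _op_combine(env, stmt):
    kw = env.kwargs(stmt)
    names = [s.strip() for s in str(kw["tracks"]).split(",")]
    weights = [float(s) for s in str(kw["weights"]).split(",")]
    return ops.combine_tracks([env.repo.get(n) for n in names], weights)


@operation("numeric_to_regions")
def _op_numeric_to_regions(env, stmt):
    kw = env.kwargs(stmt)
    return ops.numeric_to_regions(kw["track"], float(kw["threshold"]),
                                  int(kw.get("min_length", 1)),
                                  kw.get("type", "run"))


@operation("regions_to_numeric")
def _op_regions_to_numeric(env, stmt):
    kw = env.kwargs(stmt)
    return ops.regions_to_numeric(kw["track"], kw.get("mode", "coverage"))


@operation("sequence_statistic")
def _op_seq_stat(env, stmt):
    kw = env.kwargs(stmt)
    return ops.sequence_statistic(kw["dna"], kw.get("stat", "gc_content"),
                                  kw.get("base"))


@operation("collection_from_map")
def _op_coll_from_map(env, stmt):
    kw = env.kwargs(stmt)
    return ops.collection_from_map(kw["map"], kw["op"], float(kw["value"]))


@operation("normalize_priors")
def _op_norm_priors(env, stmt):
    kw = env.kwargs(stmt)
    return priors_ops.normalize_priors(kw["track"])


@operation("discriminative_prior")
def _op_disc_prior(env, stmt):
    kw = env.kwargs(stmt)
    q = kw.get("control_mean")
    if q is None:
        q = priors_ops.control_mean(kw["control"])
    return priors_ops.discriminative_prior(kw["priors"], float(q))


@operation("count_occurrences")
def _op_count(env, stmt):
    kw = env.kwargs(stmt)
    return analysis.count_motif_occurrences(kw["track"], kw.get("sequences"))


@operation("frequency_map")
def _op_freq_map(env, stmt):
    # per-motif sites-per-bp from a count analysis over control sequences;
    # +1 Laplace pseudocount keeps unseen motifs at a small nonzero rate
    kw = env.kwargs(stmt)
    counts: analysis.AnalysisResult = kw["counts"]
    total_bp = int(kw["total_bp"])
    return NumericMap("motif",
                      {m: (counts.table.loc[m, "total"] + 1) / total_bp
                       for m in counts.members},
                      default=1.0 / total_bp)


@operation("total_length")
def _op_total_length(env, stmt):
    kw = env.kwargs(stmt)
    track = kw["track"]
    return NumericMap("global",
                      {"total": float(sum(s.length for s in track.sequences))})


@operation("overrepresentation")
def _op_overrep(env, stmt):
    kw = env.kwargs(stmt)
    total_bp = kw["total_bp"]
    if isinstance(total_bp, NumericMap):
        total_bp = total_bp["total"]
    return analysis.overrepresentation(kw["counts"], kw["expected"],
                                       int(total_bp), float(kw.get("alpha", 0.05)),
                                       kw.get("correction", "bonferroni"))


@operation("group_comparison")
def _op_group_cmp(env, stmt):
    kw = env.kwargs(stmt)
    return analysis.group_comparison(kw["track"], kw["groupA"], kw["groupB"],
                                     float(kw.get("alpha", 0.05)))


@operation("positional_distribution")
def _op_posdist(env, stmt):
    kw = env.kwargs(stmt)
    return analysis.positional_distribution(kw["track"], kw.get("anchor", "tss"),
                                            int(kw.get("bin_size", 50)))


@operation("sites_vs_numeric")
def _op_sites_vs_numeric(env, stmt):
    kw = env.kwargs(stmt)
    return analysis.sites_vs_numeric(kw["track"], kw["feature"],
                                     kw.get("stat", "mean"))


@operation("rank_sum")
def _op_rank_sum(env, stmt):
    kw = env.kwargs(stmt)
    maps = []
    for chunk in str(kw["maps"]).split(","):
        name, direction = chunk.strip().split(":")
        maps.append((env.repo.get(name), direction))
    return analysis.rank_sum(maps)


@operation("map_from_result")
def _op_map_from_result(env, stmt):
    kw = env.kwargs(stmt)
    return kw["result"].to_numeric_map(kw["column"])


@operation("collate")
def _op_collate(env, stmt):
    kw = env.kwargs(stmt)
    pairs = []
    for chunk in str(kw["from"]).split(";"):
        name, cols = chunk.strip().split(":")
        pairs.append((env.repo.get(name), [c.strip() for c in cols.split(",")]))
    sort_by = None
    if "sort_by" in kw:
        sort_by = []
        for chunk in str(kw["sort_by"]).split(","):
            col, direction = chunk.strip().split(":")
            sort_by.append((col, direction))
    return analysis.collate(pairs, name=kw.get("name", "meta-analysis"),
                            sort_by=sort_by)


@operation("render")
def _op_render(env, stmt):
    kw = env.kwargs(stmt)
    return TextVariable(analysis.render_result(kw["result"],
                                               kw.get("format", "raw")))


@operation("module_from_spec")
def _op_module_from_spec(env, stmt):
    kw = env.kwargs(stmt)
    return modules.module_from_spec(kw["spec"], id=kw.get("id", stmt.target))


@operation("scan_modules")
def _op_scan_modules(env, stmt):
    kw = env.kwargs(stmt)
    return modules.scan_modules(kw["track"], kw["model"],
                                score_mode=kw.get("score_mode", "sum"))


@operation("interaction_filter")
def _op_interaction_filter(env, stmt):
    kw = env.kwargs(stmt)
    partners = kw["partners"]
    if isinstance(partners, MotifCollectionObj):
        partners = partners.partner_map()
    return modules.interaction_filter(kw["track"], partners, int(kw["max_gap"]))


@operation("read_track")
def _op_read_track(env, stmt):
    kw = env.kwargs(stmt)
    return track_io.read_track(kw["path"], kw["format"], kw["sequences"])


@operation("write_track")
def _op_write_track(env, stmt):
    kw = env.kwargs(stmt)
    track_io.write_track(kw["track"], kw["path"], kw["format"])
    return TextVariable(f"written {kw['path']}")


@operation("read_motifs")
def _op_read_motifs(env, stmt):
    kw = env.kwargs(stmt)
    return track_io.read_motifs(kw["path"], kw["format"])


# ------------------------------------------------------- external tool adapter

@dataclass
class ToolSlot:
    name: str
    data_type: str  # dna | regions | numeric | motifs
    format: str


@dataclass
class ToolConfig:
    """Declarative description of an external command-line program."""

    name: str
    command: str
    inputs: List[ToolSlot]
    outputs: List[ToolSlot]
    params: Dict[str, str]  # name -> default (as text)

    @classmethod
    def from_xml(cls, path) -> "ToolConfig":
        tree = ET.parse(path)
        root = tree.getroot()
        command_el = root.find("command")
        if command_el is None or not (command_el.text or "").strip():
            raise CiskitError(f"{path}: tool config has no <command>")
        command = command_el.text.strip()
        inputs = [ToolSlot(e.attrib["name"], e.attrib["type"], e.attrib["format"])
                  for e in root.findall("input")]
        outputs = [ToolSlot(e.attrib["name"], e.attrib["type"], e.attrib["format"])
                   for e in root.findall("output")]
        params = {e.attrib["name"]: e.attrib.get("default", "")
                  for e in root.findall("param")}
        config = cls(root.attrib.get("name", "tool"), command, inputs, outputs, params)
        config.validate()
        return config

    def placeholders(self) -> List[str]:
        return re.findall(r"\{(\w+)\}", self.command)

    def validate(self) -> None:
        declared = ({s.name for s in self.inputs} | {s.name for s in self.outputs}
                    | set(self.params))
        unbound = [p for p in self.placeholders() if p not in declared]
        if unbound:
            raise CiskitError(f"tool {self.name!r}: unbound placeholders {unbound}")


_WRITERS = {"dna": "fasta", "regions": "gff", "numeric": "wig"}


def run_external_tool(config: ToolConfig, inputs: Dict[str, object],
                      params: Optional[Dict[str, object]] = None,
                      workdir: str = ".") -> Dict[str, object]:
    """Run an external program through its declared file slots.

    Inputs are serialized to the declared formats in ``workdir``, the
    command template is filled and executed, and declared outputs are
    parsed back into data objects.  A missing executable fails before
    any file is written; a nonzero exit or unparseable output fails with
    the captured diagnostics.
    """
    params = dict(config.params, **{k: str(v) for k, v in (params or {}).items()})
    binding: Dict[str, str] = dict(params)
    for slot in config.inputs + config.outputs:
        binding[slot.name] = os.path.join(workdir, f"{slot.name}.{slot.format}")
    command = config.command.format(**binding)
    argv = shlex.split(command)
    exe = argv[0]
    if shutil.which(exe) is None and not os.path.exists(exe):
        raise CiskitError(f"tool {config.name!r}: executable {exe!r} not found")

    sequences = None
    for slot in config.inputs:
        obj = inputs.get(slot.name)
        if obj is None:
            raise CiskitError(f"tool {config.name!r}: missing input {slot.name!r}")
        track_io.write_track(obj, binding[slot.name], slot.format)
        if sequences is None and hasattr(obj, "sequences"):
            sequences = obj.sequences

    proc = subprocess.run(argv, capture_output=True, text=True, cwd=workdir)
    if proc.returncode != 0:
        raise CiskitError(f"tool {config.name!r} exited with {proc.returncode}; "
                          f"stdout: {proc.stdout!r}; stderr: {proc.stderr!r}")
    results: Dict[str, object] = {}
    for slot in config.outputs:
        path = binding[slot.name]
        if not os.path.exists(path):
            raise CiskitError(f"tool {config.name!r}: declared output {slot.name!r} "
                              f"was not produced; stdout: {proc.stdout!r}; "
                              f"stderr: {proc.stderr!r}")
        try:
            if slot.data_type == "motifs":
                results[slot.name] = track_io.read_motifs(path, slot.format)
            else:
                if sequences is None:
                    raise CiskitError("no input track to supply sequence context")
                results[slot.name] = track_io.read_track(path, slot.format, sequences)
        except CiskitError as exc:
            raise CiskitError(f"tool {config.name!r}: cannot parse output "
                              f"{slot.name!r}: {exc}") from exc
    return results
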