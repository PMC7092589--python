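"""Brute-force interpreter of the five replication-feature rules.

A deliberately plain, per-position transcription of the calling rules,
kept independent of the package's run-length implementation so the two
can be compared on random rank profiles:

* same-rank run flanked on both sides by later (higher-rank) bins -> IZ;
* same-rank run flanked on both sides by earlier bins -> termination_small
  when it spans <= 2 bins, late_CTR when it spans > 2;
* runs with an earlier flank on one side and a later flank on the other
  are slope elements; consecutive slope elements (necessarily monotone)
  form a chain, extended by a single-bin run at the very start/end of the
  segment; if the chain spans >= min_ttr_bins bins, its single-bin runs
  are TTR_right (ascending) / TTR_left (descending) and its multi-bin
  runs are breakages; shorter chains stay unlabelled;
* runs needing a flank beyond the segment end stay unlabelled.
"""


def oracle_labels(ranks, min_ttr_bins=3):
    ranks = list(ranks)
    n = len(ranks)
    labels = ["unlabelled"] * n

    # maximal equal runs, found by plain scanning
    starts = []
    for b in range(n):
        if b == 0 or ranks[b] != ranks[b - 1]:
            starts.append(b)
    runs = []
    for idx, s in enumerate(starts):
        e = starts[idx + 1] - 1 if idx + 1 < len(starts) else n - 1
        runs.append((s, e))

    def left_of(run):
        s, _ = run
        return ranks[s - 1] if s > 0 else None

    def right_of(run):
        _, e = run
        return ranks[e + 1] if e < n - 1 else None

    kinds = []
    for run in runs:
        lv, rv = left_of(run), right_of(run)
        v = ranks[run[0]]
        if lv is None or rv is None:
            kinds.append("end")
        elif lv > v and rv > v:
            kinds.append("peak_flanked_later")
        elif lv < v and rv < v:
            kinds.append("valley_flanked_earlier")
        else:
            kinds.append("slope")

    for kind, (s, e) in zip(kinds, runs):
        if kind == "peak_flanked_later":
            for b in range(s, e + 1):
                labels[b] = "IZ"
        elif kind == "valley_flanked_earlier":
            lab = "termination_small" if e - s + 1 <= 2 else "late_CTR"
            for b in range(s, e + 1):
                labels[b] = lab

    # slope chains
    m = len(runs)
    used = [False] * m
    for start in range(m):
        if kinds[start] != "slope" or used[start]:
            continue
        stop = start
        while stop + 1 < m and kinds[stop + 1] == "slope":
            stop += 1
        members = list(range(start, stop + 1))
        for c in members:
            used[c] = True
        # a lone single-bin run at the segment boundary continues the slope
        if start == 1 and kinds[0] == "end" and runs[0][0] == runs[0][1]:
            members = [0] + members
        if stop == m - 2 and kinds[m - 1] == "end" and runs[m - 1][0] == runs[m - 1][1]:
            members = members + [m - 1]
        span = sum(runs[c][1] - runs[c][0] + 1 for c in members)
        if span < min_ttr_bins:
            continue
        ascending = ranks[runs[members[0]][0]] < ranks[runs[members[-1]][0]]
        ttr = "TTR_right" if ascending else "TTR_left"
        for c in members:
            s, e = runs[c]
            lab = ttr if s == e else "breakage"
            for b in range(s, e + 1):
                labels[b] = lab
    return labels
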