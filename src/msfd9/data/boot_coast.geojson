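{
  "type": "Feature",
  "properties": {"name": "boot_coast", "note": "synthetic stylized subregion: an L-shaped shelf flanking a peninsular coast"},
  "geometry": {
    "type": "Polygon",
    "coordinates": [[
      [8.0, 36.0], [14.5, 36.0], [14.5, 38.2], [10.5, 38.2],
      [10.5, 42.5], [8.0, 42.5], [8.0, 36.0]
    ]]
  }
}
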