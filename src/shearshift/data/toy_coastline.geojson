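{"type": "Feature", "properties": {"role": "land"}, "geometry": {"type": "MultiPolygon", "coordinates": [[[[-5.3, 35.4], [42.0, 35.4], [42.0, 30.0], [-5.3, 30.0], [-5.3, 35.4]]], [[[-10.1, 44.1], [-0.6, 44.1], [-0.6, 47.9], [-4.6, 47.9], [-4.6, 49.6], [-0.6, 49.6], [-0.6, 60.0], [42.0, 60.0], [42.0, 43.4], [0.1, 43.4], [0.1, 35.9], [-10.1, 35.9], [-10.1, 44.1]]]]}}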