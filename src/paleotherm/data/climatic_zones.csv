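zone,depth,t_min_c,t_max_c,lat_min_deg,lat_max_deg,note
tropical,shallow,20,35,0,25,published shallow-water habitat range for the equatorial/tropical belt
subtropical,shallow,18,25,25,35,published shallow-water habitat range for the subtropics
warm_temperate,shallow,12,20,35,50,published shallow-water range for middle latitudes
cool_temperate,shallow,4,10,50,65,published shallow-water range for high latitudes
polar,shallow,0,4,65,90,published shallow-water range for polar regions
tropical,deep,5,12,0,25,upper bound published; lower bound an operational convention
warm_temperate,deep,5,7,35,50,published deep-water (250-500 m) range for middle latitudes
cool_temperate,deep,1,4,50,65,published range above 60 degrees latitude
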