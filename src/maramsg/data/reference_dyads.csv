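species_a,species_b,valence_low,valence_intermediate,valence_high,d_li,d_lh,d_ih,published_scenario
Ela,Zeb,preference,preference,preference,up,up,up,1
Ela,Tho,none,none,preference,ns,up,up,1
Ela,War,none,none,preference,ns,up,up,1
Ela,Imp,none,none,preference,ns,up,up,1
Imp,Har,none,none,preference,ns,up,up,1
War,Har,none,none,preference,ns,up,up,1
Ela,Gra,none,none,none,ns,up,up,1
Tho,Zeb,preference,none,preference,ns,up,up,1
War,Top,none,none,preference,up,ns,up,1
Imp,Tho,preference,preference,preference,up,up,ns,3
War,Buf,avoidance,none,none,ns,up,ns,3
Top,Gra,none,preference,preference,up,ns,ns,3
Gra,Ost,preference,none,none,down,down,ns,4
War,Tho,preference,none,none,down,down,ns,4
Zeb,Gra,preference,none,none,down,down,ns,4
Ela,Buf,preference,none,preference,down,down,up,5
Tho,Har,none,preference,none,up,ns,down,6
Tho,Top,preference,preference,preference,up,up,down,6
Top,Har,none,preference,none,up,ns,down,6
Top,Imp,none,preference,preference,up,up,down,6
Top,Ost,none,preference,none,up,ns,down,6
Top,Zeb,preference,preference,preference,up,ns,down,6
Zeb,Gir,none,preference,none,up,ns,down,6
Zeb,Har,preference,preference,none,up,ns,down,6
Zeb,Ost,none,preference,none,up,ns,down,6
Gra,Har,none,preference,none,up,down,down,6
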