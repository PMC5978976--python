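table,kvp,cu_mm,geometry,angle_deg,measured_mGy,predicted_mGy,percent_error_printed
2,50,0.0,phantom,0,65.6,61.2,-6.6
2,80,0.0,phantom,0,179.8,171.8,-4.5
2,100,0.0,phantom,0,276.5,266.1,-3.8
2,50,0.2,phantom,0,13.0,10.9,-16.1
2,80,0.2,phantom,0,61.9,57.8,-6.7
2,100,0.2,phantom,0,108.2,101.7,-6.0
2,50,0.6,phantom,0,1.7,1.6,-6.5
2,80,0.6,phantom,0,21.5,19.9,-7.5
2,100,0.6,phantom,0,43.8,45.2,3.2
3,50,0.0,phantom+table,0,57.3,54.7,-4.6
3,80,0.0,phantom+table,0,175.8,162.2,-7.7
3,100,0.0,phantom+table,0,266.8,255.8,-4.1
3,50,0.2,phantom+table,0,12.0,10.4,-13.4
3,80,0.2,phantom+table,0,62.3,57.1,-8.3
3,100,0.2,phantom+table,0,110.6,102.1,-7.7
3,50,0.6,phantom+table,0,1.6,1.6,-4.4
3,80,0.6,phantom+table,0,22.2,20.3,-8.7
3,100,0.6,phantom+table,0,45.7,46.4,1.5
4,50,0.0,phantom+table+pad,0,49.9,47.8,-4.1
4,80,0.0,phantom+table+pad,0,151.8,142.7,-6.0
4,100,0.0,phantom+table+pad,0,229.3,225.5,-1.6
4,50,0.2,phantom+table+pad,0,10.3,9.2,-10.5
4,80,0.2,phantom+table+pad,0,57.3,50.6,-11.8
4,100,0.2,phantom+table+pad,0,101.0,90.4,-10.5
4,50,0.6,phantom+table+pad,0,1.5,1.4,-5.7
4,80,0.6,phantom+table+pad,0,20.2,17.9,-11.2
4,100,0.6,phantom+table+pad,0,41.4,41.0,-0.9
5,80,0.2,phantom+table,0,45.2,48.1,6.6
5,80,0.2,phantom+table,30,43.2,46.4,7.5
5,80,0.2,phantom+table,60,36.9,36.9,-0.1
5,80,0.2,phantom+table+pad,0,41.8,40.8,-2.5
5,80,0.2,phantom+table+pad,30,40.7,38.5,-5.2
5,80,0.2,phantom+table+pad,60,31.2,27.8,-11.0
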