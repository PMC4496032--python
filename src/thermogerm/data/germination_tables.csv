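cultivar,t_cool_c,t_warm_c,mean_pct,sd_pct,n_reps,n_seeds
Midnight II,5,5,0.0,0.0,3,50
Midnight II,5,10,0.0,0.0,3,50
Midnight II,5,15,0.0,0.0,3,50
Midnight II,5,20,6.0,4.0,3,50
Midnight II,5,25,50.7,5.0,3,50
Midnight II,5,30,43.3,9.0,3,50
Midnight II,5,35,0.0,0.0,3,50
Midnight II,5,40,0.7,1.2,3,50
Midnight II,10,10,6.0,0.0,3,50
Midnight II,10,15,16.7,2.3,3,50
Midnight II,10,20,28.0,2.0,3,50
Midnight II,10,25,66.7,4.3,3,50
Midnight II,10,30,74.0,3.5,3,50
Midnight II,10,35,0.0,0.0,3,50
Midnight II,10,40,0.0,0.0,3,50
Midnight II,15,15,25.3,7.0,3,50
Midnight II,15,20,46.0,6.9,3,50
Midnight II,15,25,78.0,6.0,3,50
Midnight II,15,30,72.0,7.2,3,50
Midnight II,15,35,34.0,6.0,3,50
Midnight II,15,40,0.0,0.0,3,50
Midnight II,20,20,23.3,9.5,3,50
Midnight II,20,25,80.7,1.2,3,50
Midnight II,20,30,81.3,8.1,3,50
Midnight II,20,35,64.0,2.0,3,50
Midnight II,20,40,0.0,0.0,3,50
Midnight II,25,25,18.7,1.3,3,50
Midnight II,25,30,78.7,10.3,3,50
Midnight II,25,35,68.7,5.8,3,50
Midnight II,25,40,0.0,0.0,3,50
Midnight II,30,30,38.7,9.0,3,50
Midnight II,30,35,24.7,4.6,3,50
Midnight II,30,40,0.0,0.0,3,50
Midnight II,35,35,0.0,0.0,3,50
Midnight II,35,40,0.0,0.0,3,50
Midnight II,40,40,0.0,0.0,3,50
Diva,5,5,0.0,0.0,3,50
Diva,5,10,0.0,0.0,3,50
Diva,5,15,0.0,0.0,3,50
Diva,5,20,6.7,1.2,3,50
Diva,5,25,44.7,2.3,3,50
Diva,5,30,44.0,8.7,3,50
Diva,5,35,0.0,0.0,3,50
Diva,5,40,0.0,0.0,3,50
Diva,10,10,6.0,0.0,3,50
Diva,10,15,13.3,4.2,3,50
Diva,10,20,35.3,3.1,3,50
Diva,10,25,77.3,3.1,3,50
Diva,10,30,73.3,17.0,3,50
Diva,10,35,0.0,0.0,3,50
Diva,10,40,0.0,0.0,3,50
Diva,15,15,14.0,2.0,3,50
Diva,15,20,52.7,4.2,3,50
Diva,15,25,79.3,6.4,3,50
Diva,15,30,82.0,5.3,3,50
Diva,15,35,40.0,3.5,3,50
Diva,15,40,0.0,0.0,3,50
Diva,20,20,20.0,2.0,3,50
Diva,20,25,82.0,5.3,3,50
Diva,20,30,81.3,8.1,3,50
Diva,20,35,69.3,8.1,3,50
Diva,20,40,0.0,0.0,3,50
Diva,25,25,26.0,4.0,3,50
Diva,25,30,78.0,8.0,3,50
Diva,25,35,53.3,4.2,3,50
Diva,25,40,0.0,0.0,3,50
Diva,30,30,35.3,7.0,3,50
Diva,30,35,38.7,3.1,3,50
Diva,30,40,0.0,0.0,3,50
Diva,35,35,0.0,0.0,3,50
Diva,35,40,0.0,0.0,3,50
Diva,40,40,0.0,0.0,3,50
Rugby II,5,5,0.0,0.0,3,50
Rugby II,5,10,0.0,0.0,3,50
Rugby II,5,15,0.0,0.0,3,50
Rugby II,5,20,18.0,3.5,3,50
Rugby II,5,25,50.7,1.2,3,50
Rugby II,5,30,49.3,4.6,3,50
Rugby II,5,35,0.0,0.0,3,50
Rugby II,5,40,0.0,0.0,3,50
Rugby II,10,10,5.3,3.1,3,50
Rugby II,10,15,11.3,6.1,3,50
Rugby II,10,20,33.3,4.2,3,50
Rugby II,10,25,68.7,6.1,3,50
Rugby II,10,30,67.3,7.0,3,50
Rugby II,10,35,0.0,0.0,3,50
Rugby II,10,40,0.0,0.0,3,50
Rugby II,15,15,15.3,3.1,3,50
Rugby II,15,20,50.7,5.0,3,50
Rugby II,15,25,84.7,6.4,3,50
Rugby II,15,30,80.7,5.0,3,50
Rugby II,15,35,50.7,11.7,3,50
Rugby II,15,40,0.0,0.0,3,50
Rugby II,20,20,26.0,2.0,3,50
Rugby II,20,25,78.7,10.3,3,50
Rugby II,20,30,85.3,6.1,3,50
Rugby II,20,35,60.0,5.3,3,50
Rugby II,20,40,0.0,0.0,3,50
Rugby II,25,25,19.3,3.1,3,50
Rugby II,25,30,78.0,8.0,3,50
Rugby II,25,35,55.3,7.0,3,50
Rugby II,25,40,0.0,0.0,3,50
Rugby II,30,30,24.7,11.0,3,50
Rugby II,30,35,27.3,15.3,3,50
Rugby II,30,40,0.0,0.0,3,50
Rugby II,35,35,0.7,1.2,3,50
Rugby II,35,40,0.0,0.0,3,50
Rugby II,40,40,0.0,0.0,3,50
Leopard,5,5,0.0,0.0,3,50
Leopard,5,10,0.0,0.0,3,50
Leopard,5,15,0.0,0.0,3,50
Leopard,5,20,10.7,3.1,3,50
Leopard,5,25,44.0,7.2,3,50
Leopard,5,30,52.7,8.1,3,50
Leopard,5,35,0.0,0.0,3,50
Leopard,5,40,0.0,0.0,3,50
Leopard,10,10,6.0,2.0,3,50
Leopard,10,15,8.7,3.1,3,50
Leopard,10,20,38.0,8.0,3,50
Leopard,10,25,63.3,3.1,3,50
Leopard,10,30,69.3,2.3,3,50
Leopard,10,35,0.0,0.0,3,50
Leopard,10,40,0.0,0.0,3,50
Leopard,15,15,19.3,3.1,3,50
Leopard,15,20,58.7,2.3,3,50
Leopard,15,25,70.7,5.0,3,50
Leopard,15,30,80.7,9.2,3,50
Leopard,15,35,44.0,2.0,3,50
Leopard,15,40,0.0,0.0,3,50
Leopard,20,20,27.3,1.2,3,50
Leopard,20,25,64.7,25.0,3,50
Leopard,20,30,87.3,3.1,3,50
Leopard,20,35,76.0,8.0,3,50
Leopard,20,40,0.0,0.0,3,50
Leopard,25,25,22.0,2.0,3,50
Leopard,25,30,79.3,5.0,3,50
Leopard,25,35,46.0,2.0,3,50
Leopard,25,40,0.0,0.0,3,50
Leopard,30,30,33.3,4.2,3,50
Leopard,30,35,52.0,7.2,3,50
Leopard,30,40,0.0,0.0,3,50
Leopard,35,35,0.0,0.0,3,50
Leopard,35,40,0.0,0.0,3,50
Leopard,40,40,0.0,0.0,3,50
Sapphire,5,5,0.0,0.0,3,50
Sapphire,5,10,0.0,0.0,3,50
Sapphire,5,15,0.0,0.0,3,50
Sapphire,5,20,4.0,2.0,3,50
Sapphire,5,25,45.3,4.2,3,50
Sapphire,5,30,47.3,3.1,3,50
Sapphire,5,35,0.0,0.0,3,50
Sapphire,5,40,0.0,0.0,3,50
Sapphire,10,10,6.0,0.0,3,50
Sapphire,10,15,10.0,0.0,3,50
Sapphire,10,20,38.0,6.0,3,50
Sapphire,10,25,65.3,5.0,3,50
Sapphire,10,30,61.3,5.0,3,50
Sapphire,10,35,0.0,0.0,3,50
Sapphire,10,40,0.0,0.0,3,50
Sapphire,15,15,24.7,6.1,3,50
Sapphire,15,20,58.0,10.0,3,50
Sapphire,15,25,77.3,7.0,3,50
Sapphire,15,30,80.0,3.5,3,50
Sapphire,15,35,46.7,11.7,3,50
Sapphire,15,40,0.0,0.0,3,50
Sapphire,20,20,26.0,2.0,3,50
Sapphire,20,25,80.7,2.3,3,50
Sapphire,20,30,85.3,3.1,3,50
Sapphire,20,35,61.3,7.0,3,50
Sapphire,20,40,0.0,0.0,3,50
Sapphire,25,25,16.0,2.0,3,50
Sapphire,25,30,79.3,5.0,3,50
Sapphire,25,35,51.3,6.4,3,50
Sapphire,25,40,0.0,0.0,3,50
Sapphire,30,30,33.3,8.3,3,50
Sapphire,30,35,43.3,7.0,3,50
Sapphire,30,40,0.0,0.0,3,50
Sapphire,35,35,0.0,0.0,3,50
Sapphire,35,40,0.0,0.0,3,50
Sapphire,40,40,0.0,0.0,3,50
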